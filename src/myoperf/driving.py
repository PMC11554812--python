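"""Time-periodic driving pressures: ventricular, aortic and intramyocardial.

The contraction of the ventricle enters the perfusion model only through the
intramyocardial pressure P_im(x, t), the extravascular tissue pressure that
squeezes the intramural vessels.  Its time course tracks the left-ventricular
chamber pressure P_LV(t) and decreases linearly across the wall:

    P_im(x, t) = [f_endo − (f_endo − f_epi)·λ(x)] · P_LV(t),

with λ the normalized transmural coordinate (0 at the endocardium) and the
experimentally supported factors f_endo = 0.9, f_epi = 0.3.

P_LV and the aortic (inlet) pressure are represented by a parametric C¹
waveform family — a smoothstep rise/plateau/fall bump over the systolic
interval on a baseline — personalized by exactly two knobs: the peak value
and the systolic interval (fraction of the period).  Tabulated waveforms
(e.g. digitized from measurements or an electromechanics run) can be imported
from CSV and bypass the parametric family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MMHG_TO_PA

ENDO_FACTOR_DEFAULT = 0.9
EPI_FACTOR_DEFAULT = 0.3
DIASTOLIC_LV_BASELINE = 8.0 * MMHG_TO_PA  # Pa


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


class PressureWaveform:
    """Periodic pressure waveform p(t) in Pa with period T.

    Either analytic (piecewise smoothstep, built by the factory functions
    below) or interpolated from samples with a periodic cubic spline.
    """

    def __init__(self, period: float, func=None, samples=None):
        if period <= 0:
            raise ValueError("period must be positive")
        self.period = float(period)
        if (func is None) == (samples is None):
            raise ValueError("provide exactly one of func or samples")
        if func is not None:
            self._func = func
        else:
            from scipy.interpolate import CubicSpline
            t, v = np.asarray(samples[0], float), np.asarray(samples[1], float)
            if not np.isclose(v[0], v[-1], rtol=1e-8, atol=1e-8):
                raise ValueError("sampled waveform must be periodic "
                                 "(first and last values equal)")
            v = v.copy()
            v[-1] = v[0]
            spl = CubicSpline(t, v, bc_type="periodic")
            self._func = spl

    def __call__(self, t):
        tt = np.asarray(t, dtype=float) % self.period
        out = self._func(tt)
        return float(out) if np.ndim(t) == 0 else np.asarray(out, float)

    def sample(self, n: int = 512):
        """Return (t, p) over one period with n+1 points (endpoint included)."""
        t = np.linspace(0.0, self.period, n + 1)
        return t, self(t)

    def mean(self, n: int = 4096) -> float:
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return float(np.mean(self(t)))

    def to_csv(self, path, n: int = 512):
        """Export one period as CSV with t in s and p in mmHg."""
        import pandas as pd
        t, p = self.sample(n)
        pd.DataFrame({"t_s": t, "p_mmHg": p / MMHG_TO_PA}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PressureWaveform":
        """Import a tabulated waveform (columns t_s, p_mmHg)."""
        import pandas as pd
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(float)
        p = df["p_mmHg"].to_numpy(float) * MMHG_TO_PA
        return cls(period=float(t[-1] - t[0]), samples=(t - t[0], p))


def build_plv_waveform(peak: float, period: float, systolic_fraction: float = 0.37,
                       diastolic_baseline: float = DIASTOLIC_LV_BASELINE,
                       rise_fraction: float = 0.3, fall_fraction: float = 0.2,
                       ) -> PressureWaveform:
    """Parametric left-ventricular pressure: baseline with a systolic bump.

    The systole occupies ``systolic_fraction`` of the period starting at
    t = 0: a smoothstep rise over ``rise_fraction`` of the systole, a plateau
    at exactly ``peak``, and a smoothstep fall; the rest of the cycle sits at
    ``diastolic_baseline``.  All pressures in Pa.
    """
    if not 0 < systolic_fraction < 1:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if not 0 <= diastolic_baseline < peak:
        raise ValueError(f"baseline ({diastolic_baseline}) must be in [0, peak)")
    if rise_fraction + fall_fraction >= 1:
        raise ValueError("rise and fall fractions must sum to < 1")
    ts = systolic_fraction * period
    t_rise, t_fall = rise_fraction * ts, fall_fraction * ts
    amp = peak - diastolic_baseline

    def f(t):
        t = np.asarray(t, float)
        up = _smoothstep(t / t_rise)
        down = _smoothstep((ts - t) / t_fall)
        bump = np.where(t < ts, np.minimum(up, down), 0.0)
        return diastolic_baseline + amp * bump

    wf = PressureWaveform(period, func=f)
    # the flow-phase "systole" is the ejection interval: it ends at aortic
    # valve closure, i.e. at the onset of the terminal relaxation ramp, while
    # the chamber pressure keeps decaying into early diastole
    wf.systolic_window = (0.0, ts - t_fall)
    return wf


def build_aortic_waveform(peak: float, period: float, systolic_fraction: float = 0.37,
                          mean_target: float | None = None,
                          diastolic_pressure: float | None = None,
                          decay_fraction: float = 0.6, lag: float = 0.0,
                          ) -> PressureWaveform:
    """Parametric aortic (coronary inlet) pressure waveform, Pa.

    Systolic smoothstep rise to ``peak`` followed by a slow smoothstep decay
    extending ``decay_fraction`` of the diastole down to
    ``diastolic_pressure`` (default 0.55·peak), where it stays until the next
    beat.  ``lag`` shifts the waveform relative to the ventricular one (valve
    timing).  If ``mean_target`` is given the curve is affinely contracted
    toward the peak so its time average matches it.
    """
    if not 0 < systolic_fraction < 1:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    dia = 0.55 * peak if diastolic_pressure is None else diastolic_pressure
    if not 0 < dia < peak:
        raise ValueError(f"diastolic pressure ({dia}) must be in (0, peak)")
    ts = systolic_fraction * period
    t_decay_end = ts + decay_fraction * (period - ts)
    amp = peak - dia

    def base(t):
        t = np.asarray(t, float)
        up = _smoothstep(t / (0.4 * ts))
        down = _smoothstep((t_decay_end - t) / (t_decay_end - 0.4 * ts))
        bump = np.where(t < t_decay_end, np.minimum(up, down), 0.0)
        return dia + amp * bump

    func = base
    if mean_target is not None:
        if mean_target >= peak:
            raise ValueError("mean_target must be below the systolic peak")
        tgrid = np.linspace(0.0, period, 4096, endpoint=False)
        base_mean = float(np.mean(base(tgrid)))
        scale = (peak - mean_target) / (peak - base_mean)

        def func(t):  # affine contraction toward the peak
            return peak - scale * (peak - base(t))

    if lag:
        inner = func

        def func(t):
            return inner((np.asarray(t, float) - lag) % period)

    final = func
    wf = PressureWaveform(period, func=lambda t: final(t))
    wf.systolic_window = (lag % period, (ts + lag) % period if (ts + lag) % period else ts)
    return wf


@dataclass
class PimField:
    """Space-time intramyocardial pressure with linear transmural modulation."""

    waveform: PressureWaveform
    transmural: np.ndarray  # λ per node
    endo_factor: float = ENDO_FACTOR_DEFAULT
    epi_factor: float = EPI_FACTOR_DEFAULT

    def __post_init__(self):
        self.transmural = np.asarray(self.transmural, dtype=float)

    @property
    def spatial_factor(self) -> np.ndarray:
        """Per-node ratio P_im/P_LV: f_endo at λ=0 down to f_epi at λ=1."""
        return self.endo_factor - (self.endo_factor - self.epi_factor) * self.transmural


def evaluate_pim(field: PimField, t) -> np.ndarray:
    """Nodal P_im(·, t) in Pa."""
    return field.spatial_factor * field.waveform(t)


def pim_time_derivative(field: PimField, t, dt: float) -> np.ndarray:
    """The discrete rate (P_im(t+Δt) − P_im(t))/Δt used by the solver, Pa/s."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return field.spatial_factor * (field.waveform(t + dt) - field.waveform(t)) / dt
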