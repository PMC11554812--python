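"""Desk-scale in-silico studies: rigid-vs-compliant and parameter sweeps.

Both studies run on an idealized wall with a handful of synthetic outlets of
heterogeneous radii, since patient coronary trees are out of scope.  The
rigid comparison freezes every vessel cross-section at its Δp = 0 value and
zeroes the compliances, which makes arterial inflow and venous outflow
instantaneously identical and lets the inflow follow the aortic pressure
(systolic peak); the compliant model instead shows the systolic impediment:
diastolic inflow peak and systolic venous-outflow peak.

The sensitivity sweeps vary the specific permeability κ, a homogeneous scale
on the length densities (nL)_i, a homogeneous scale on the morphometry
factors δ_i, or per-compartment (nL) scale vectors, and summarize each run by
global mean MBF, regional (per-territory) MBF variance, phase-split mean
inflows and the mean arteriolar pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coronary0d as cor
from . import postprocess as post
from .driving import PimField, build_aortic_waveform, build_plv_waveform
from .params import ParameterSet
from .simulate import run_heartbeats
from .territories import OutletSpec, partition

ML_MIN = 1e6 * 60.0  # m³/s → ml/min


def default_outlets(mesh, n: int = 4, seed: int = 0) -> list:
    """Synthetic epicardial outlets with heterogeneous radii on the epi face.

    Outlets are spread over the epicardial surface (largest-z face for a
    slab) on a deterministic low-discrepancy pattern; radii cycle through a
    fixed heterogeneous set scaled to typical epicardial calibers.
    """
    rng = np.random.default_rng(seed)
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    radii = np.array([1.5, 0.8, 1.2, 0.6, 1.0, 0.9, 1.4, 0.7])
    # jittered grid over the epi plane for well-separated seeds
    m = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(lo[0], hi[0], m + 2)[1:-1]
    ys = np.linspace(lo[1], hi[1], m + 2)[1:-1]
    pts = [(x, y) for x in xs for y in ys][:n]
    jitter = rng.uniform(-0.05, 0.05, size=(n, 2)) * (hi[:2] - lo[:2])
    return [OutletSpec(k + 1, (pts[k][0] + jitter[k, 0],
                               pts[k][1] + jitter[k, 1], hi[2]),
                       float(radii[k % len(radii)]))
            for k in range(n)]


def build_run(mesh, params: ParameterSet, outlets=None, *, seed: int = 0,
              pim_uniform: bool = False):
    """Assemble territories, waveforms, P_im field and outlet network."""
    if outlets is None:
        outlets = default_outlets(mesh, seed=seed)
    tmap = partition(mesh, outlets)
    plv = build_plv_waveform(params.peak_pressure, params.period,
                             params.systolic_fraction)
    aortic = build_aortic_waveform(params.peak_pressure, params.period,
                                   params.systolic_fraction)
    lam = mesh.require_transmural()
    if pim_uniform:
        pim_field = PimField(plv, lam, endo_factor=0.6, epi_factor=0.6)
    else:
        pim_field = PimField(plv, lam)
    network = cor.OutletNetwork(outlets, params.coupling_conductance, aortic)
    return tmap, pim_field, network


def run_case(mesh, params: ParameterSet, outlets=None, *, rigid: bool = False,
             seed: int = 0, max_beats: int = 10, cycle_tol: float = 0.01,
             n_beats=None):
    """One full simulation on the idealized wall; returns a SimulationResult."""
    tmap, pim_field, network = build_run(mesh, params, outlets, seed=seed)
    return run_heartbeats(mesh, params, tmap, network, pim_field, rigid=rigid,
                          max_beats=max_beats, cycle_tol=cycle_tol,
                          n_beats=n_beats)


@dataclass
class RigidComparison:
    """Paired compliant/rigid runs with their waveforms and ratio tables."""

    compliant: object
    rigid: object
    compliant_ratios: dict
    rigid_ratios: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, ratios in (("compliant", self.compliant_ratios),
                             ("rigid", self.rigid_ratios)):
            rows.append({"model": name, **ratios})
        return pd.DataFrame(rows)


def compare_rigid(mesh, params: ParameterSet, outlets=None, *, seed: int = 0,
                  max_beats: int = 10, cycle_tol: float = 0.01,
                  n_beats=None) -> RigidComparison:
    """Run the compliant and rigid models on identical inputs and compare."""
    if outlets is None:
        outlets = default_outlets(mesh, seed=seed)
    res_c = run_case(mesh, params, outlets, rigid=False, seed=seed,
                     max_beats=max_beats, cycle_tol=cycle_tol, n_beats=n_beats)
    res_r = run_case(mesh, params, outlets, rigid=True, seed=seed,
                     max_beats=max_beats, cycle_tol=cycle_tol, n_beats=n_beats)
    ratios_c = post.flow_ratios(res_c.times, res_c.total_inflow,
                                res_c.systolic_window)
    ratios_r = post.flow_ratios(res_r.times, res_r.total_inflow,
                                res_r.systolic_window)
    return RigidComparison(res_c, res_r, ratios_c, ratios_r)


@dataclass
class SweepSpec:
    """One-parameter sensitivity sweep definition."""

    parameter: str  # kappa | nL_scale | delta_scale | nL_per_compartment
    values: list
    base: ParameterSet = field(default_factory=ParameterSet)
    seed: int = 0

    def __post_init__(self):
        allowed = {"kappa", "nL_scale", "delta_scale", "nL_per_compartment"}
        if self.parameter not in allowed:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}; "
                             f"choose from {sorted(allowed)}")
        if not len(self.values):
            raise ValueError("sweep values must be nonempty")
        for v in self.values:
            arr = np.atleast_1d(np.asarray(v, float))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite sweep value {v!r}")
            if self.parameter == "nL_per_compartment" and arr.shape != (3,):
                raise ValueError("per-compartment scenarios need 3 entries")


def _apply(spec: SweepSpec, value) -> ParameterSet:
    base = spec.base
    if spec.parameter == "kappa":
        return base.replace(specific_permeability=float(value))
    if spec.parameter == "nL_scale":
        return base.replace(length_density=tuple(np.array(base.nL) * float(value)))
    if spec.parameter == "delta_scale":
        return base.replace(morphometry_factor=tuple(np.array(base.delta) * float(value)))
    scale = np.asarray(value, float)
    return base.replace(length_density=tuple(np.array(base.nL) * scale))


def summarize_run(result) -> dict:
    """Sweep summary metrics for one converged run."""
    mbf = post.mbf_map(result)
    inflow = result.total_inflow * ML_MIN
    mask = post.systolic_mask(result.times, result.systolic_window)
    nv = result.mesh.node_volumes
    p2_space = result.p_history[:, 1, :] @ nv / nv.sum()  # space-mean p₂(t)
    sys_on = result.systolic_window
    dia_mask = ~mask
    return {
        "global_mean_mbf": mbf.global_mean,
        "regional_mbf_variance": mbf.territory_variance(),
        "systolic_mean_inflow_ml_min": float(inflow[mask].mean()),
        "diastolic_mean_inflow_ml_min": float(inflow[dia_mask].mean()),
        "mean_arteriolar_pressure_mmHg": float(p2_space.mean() / 133.322),
        "diastolic_arteriolar_pressure_mmHg": float(p2_space[dia_mask].mean()
                                                    / 133.322),
        "systole_on_s": sys_on[0], "systole_off_s": sys_on[1],
        "beats": result.report.beats,
    }


def sensitivity_sweep(spec: SweepSpec, mesh, outlets=None, *,
                      max_beats: int = 8, cycle_tol: float = 0.01,
                      n_beats=None) -> pd.DataFrame:
    """Run the sweep and return one tidy summary row per parameter value.

    Non-convergent members are recorded as failed rows and the sweep
    continues.
    """
    if outlets is None:
        outlets = default_outlets(mesh, seed=spec.seed)
    rows = []
    for value in spec.values:
        params = _apply(spec, value)
        row = {"parameter": spec.parameter,
               "value": (list(np.atleast_1d(value).astype(float))
                         if spec.parameter == "nL_per_compartment"
                         else float(value))}
        try:
            result = run_case(mesh, params, outlets, seed=spec.seed,
                              max_beats=max_beats, cycle_tol=cycle_tol,
                              n_beats=n_beats)
            row.update(summarize_run(result))
            row["status"] = "ok"
        except (FloatingPointError, RuntimeError) as exc:
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
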