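"""Pressure–area constitutive laws of the intramural compartments.

Each homogenized compartment (1 = small arteries, 2 = arterioles,
3 = capillaries) carries a mean vessel cross-sectional area A_i that depends
on the transluminal pressure Δp = p_i − P_im (intraluminal minus
intramyocardial), with Δp in Pa and A_i in mm².  The laws describe the fully
passive (hyperemic) wall:

* small arteries are rigid:            A₁ = 0.07 mm²
* arterioles:  sigmoid for Δp < 0 (asymptotic minimum 0.003 mm²) joined to a
  logarithmic fit of isolated-arteriole data for Δp ≥ 0,
      A₂ = 0.0030 + 0.0050 / (1 + exp(−3.02·10⁻⁴ Δp))        (Δp < 0)
      A₂ = 0.0011 ln(1.2 Δp + 3500) − 0.0033                  (Δp ≥ 0)
* capillaries: a single sigmoid with asymptotic minimum 1 μm²,
      A₃ = 10⁻⁶ + 2.4·10⁻⁵ / (1 + exp(−3·10⁻⁴ Δp − 0.5))

The distensibility C_i is the *analytic* derivative dA_i/dΔp of the
implemented area law, so the compliance term of the porous-medium model is
exactly consistent with the porosity it differentiates; the independently
published (rounded) C_i formulas are kept as :func:`distensibility_printed`
for cross-checking.

Derived bulk coefficients (all evaluated at the local Δp):

* porosity              φ_i = (nL)_i · A_i                 (dimensionless)
* Darcy permeability    K_i = (κ/μ) · φ_i                  (m²·Pa⁻¹·s⁻¹)
* network conductance   β_i = δ_i · (nL)_i · A_i²          (Pa⁻¹·s⁻¹)
* exchange conductance  β_{i,j} = (β_i + β_j)/2 for hierarchically adjacent
  pairs (1,2) and (2,3); the non-adjacent pair (1,3) exchanges no mass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params import ParameterSet

COMPARTMENTS = (1, 2, 3)

# printed coefficients, Δp in Pa, A in mm²
_A1 = 0.07
_A2_MIN, _A2_AMP, _A2_RATE = 0.0030, 0.0050, 3.02e-4
_A2_LOG_C, _A2_LOG_S, _A2_LOG_B, _A2_LOG_OFF = 0.0011, 1.2, 3500.0, -0.0033
_A3_MIN, _A3_AMP, _A3_RATE, _A3_SHIFT = 1e-6, 2.4e-5, 3e-4, 0.5

#: hierarchically adjacent compartment pairs (unordered)
ADJACENT_PAIRS = frozenset({frozenset({1, 2}), frozenset({2, 3})})


def _check_index(i: int) -> int:
    if i not in COMPARTMENTS:
        raise ValueError(f"compartment index must be 1, 2 or 3, got {i!r}")
    return i


def area(i: int, dp) -> np.ndarray | float:
    """Mean vessel cross-section A_i(Δp) in mm²; Δp = p_i − P_im in Pa."""
    _check_index(i)
    dp = np.asarray(dp, dtype=float)
    if i == 1:
        out = np.full_like(dp, _A1)
    elif i == 2:
        sig = _A2_MIN + _A2_AMP * expit(_A2_RATE * dp)
        # log branch guarded against its own singularity far outside use range
        arg = np.maximum(_A2_LOG_S * dp + _A2_LOG_B, 1e-300)
        log = _A2_LOG_C * np.log(arg) + _A2_LOG_OFF
        out = np.where(dp < 0.0, sig, log)
    else:
        out = _A3_MIN + _A3_AMP * expit(_A3_RATE * dp + _A3_SHIFT)
    return out if out.ndim else float(out)


def distensibility(i: int, dp) -> np.ndarray | float:
    """Distensibility C_i = dA_i/dΔp in mm²·Pa⁻¹ (exact analytic derivative)."""
    _check_index(i)
    dp = np.asarray(dp, dtype=float)
    if i == 1:
        out = np.zeros_like(dp)
    elif i == 2:
        s = expit(_A2_RATE * dp)
        sig = _A2_AMP * _A2_RATE * s * (1.0 - s)
        log = _A2_LOG_C * _A2_LOG_S / np.maximum(_A2_LOG_S * dp + _A2_LOG_B, 1e-300)
        out = np.where(dp < 0.0, sig, log)
    else:
        s = expit(_A3_RATE * dp + _A3_SHIFT)
        out = _A3_AMP * _A3_RATE * s * (1.0 - s)
    return out if out.ndim else float(out)


def distensibility_printed(i: int, dp) -> np.ndarray | float:
    """The published C_i expressions (rounded coefficients), mm²·Pa⁻¹.

    Kept only as an independent cross-check of :func:`distensibility`; the
    positive-Δp arteriolar branch differs by ~1.5% from the exact derivative
    because its printed numerator is rounded to 0.0013.
    """
    _check_index(i)
    dp = np.asarray(dp, dtype=float)
    if i == 1:
        out = np.zeros_like(dp)
    elif i == 2:
        s = expit(3.02e-4 * dp)
        sig = 1.51e-6 * s * (1.0 - s)  # e/(1+e)² written in σ form
        log = 0.0013 / np.maximum(1.2 * dp + 3500.0, 1e-300)
        out = np.where(dp < 0.0, sig, log)
    else:
        s = expit(3e-4 * dp + 0.5)
        out = 7.2e-9 * s * (1.0 - s)
    return out if out.ndim else float(out)


def porosity(i: int, dp, p: ParameterSet) -> np.ndarray | float:
    """Fluid volume fraction φ_i = (nL)_i · A_i(Δp), dimensionless."""
    return p.nL[_check_index(i) - 1] * area(i, dp)


def permeability(i: int, dp, p: ParameterSet) -> np.ndarray | float:
    """Darcy permeability K_i = (κ/μ)·φ_i(Δp) in m²·Pa⁻¹·s⁻¹."""
    return (p.specific_permeability / p.blood_viscosity) * porosity(i, dp, p)


def compartment_conductance(i: int, dp, p: ParameterSet) -> np.ndarray | float:
    """Poiseuille-network conductance β_i = δ_i·(nL)_i·A_i(Δp)² in Pa⁻¹·s⁻¹."""
    k = _check_index(i) - 1
    return p.delta[k] * p.nL[k] * area(i, dp) ** 2


def exchange_conductance(i: int, j: int, dp_i, dp_j, p: ParameterSet,
                         *, all_pairs: bool = False) -> np.ndarray | float:
    """Inter-compartment conductance β_{i,j} = (β_i + β_j)/2 in Pa⁻¹·s⁻¹.

    Only hierarchically adjacent pairs (1,2) and (2,3) exchange mass: the
    tree-like intramural network has no direct artery→capillary anastomosis,
    so β_{1,3} = 0 unless ``all_pairs`` is set (which applies the averaging
    formula to every pair).
    """
    _check_index(i)
    _check_index(j)
    if i == j:
        raise ValueError("exchange conductance requires two distinct compartments")
    if not all_pairs and frozenset({i, j}) not in ADJACENT_PAIRS:
        dp_i = np.asarray(dp_i, dtype=float)
        out = np.zeros_like(dp_i)
        return out if out.ndim else 0.0
    return 0.5 * (compartment_conductance(i, dp_i, p)
                  + compartment_conductance(j, dp_j, p))


def refit_a2_sigmoid() -> tuple[float, float, float, float]:
    """Recompute the arteriolar sigmoid for C² continuity at Δp = 0.

    The negative-Δp sigmoid of the published law was fit to match value,
    slope and curvature of the logarithmic branch at the junction, but the
    printed (rounded) coefficients leave a ~3.1% value jump.  This solves for
    a shifted sigmoid  A = a_min + b·σ(k·Δp + s)  (σ the logistic function,
    a_min fixed at 0.003 mm²) whose value, first and second derivative at
    Δp = 0 equal those of the logarithmic branch exactly.

    Returns ``(a_min, b, k, s)``.  This refit is an optional smoothing mode;
    the default laws keep the printed coefficients.
    """
    from scipy.optimize import brentq

    v0 = _A2_LOG_C * np.log(_A2_LOG_B) + _A2_LOG_OFF
    c1 = _A2_LOG_C * _A2_LOG_S / _A2_LOG_B
    c2 = -_A2_LOG_C * _A2_LOG_S**2 / _A2_LOG_B**2
    dv = v0 - _A2_MIN  # = b·σ0

    # with σ0 = σ(s):  b σ0 = dv,  b k σ0(1−σ0) = c1,  b k² σ0(1−σ0)(1−2σ0) = c2
    # eliminate b, k → g(σ0) = c2·dv·σ0(1−σ0) − c1²·σ0²·(1−2σ0)/σ0 ... solve in σ0
    def g(s0):
        k = c1 / (dv * (1.0 - s0))
        return k * (1.0 - 2.0 * s0) - c2 / c1

    s0 = brentq(g, 0.5 + 1e-12, 1.0 - 1e-9)
    k = c1 / (dv * (1.0 - s0))
    b = dv / s0
    s = np.log(s0 / (1.0 - s0))
    return (_A2_MIN, b, k, s)


def area2_refit(dp, coeffs=None) -> np.ndarray | float:
    """Arteriolar area using the C²-refit sigmoid for Δp < 0 (mm²)."""
    if coeffs is None:
        coeffs = refit_a2_sigmoid()
    a_min, b, k, s = coeffs
    dp = np.asarray(dp, dtype=float)
    sig = a_min + b * expit(k * dp + s)
    arg = np.maximum(_A2_LOG_S * dp + _A2_LOG_B, 1e-300)
    log = _A2_LOG_C * np.log(arg) + _A2_LOG_OFF
    out = np.where(dp < 0.0, sig, log)
    return out if out.ndim else float(out)


def area_bounds(i: int) -> tuple[float, float]:
    """Saturation bounds (min, max) of A_i over all Δp, mm²."""
    _check_index(i)
    if i == 1:
        return (_A1, _A1)
    if i == 2:
        # log branch grows without bound in theory; physiologic range caps
        # at the value where the sigmoid would saturate
        return (_A2_MIN, _A2_MIN + _A2_AMP)
    return (_A3_MIN, _A3_MIN + _A3_AMP)


def tabulate_curves(dp_grid, path=None):
    """Tabulate (Δp, A_i, C_i) for all compartments; optionally write CSV.

    Returns a pandas DataFrame with Δp in Pa, areas in mm² and
    distensibilities in mm²·Pa⁻¹, for plotting against the published
    constitutive curves.
    """
    import pandas as pd

    dp = np.asarray(dp_grid, dtype=float)
    data = {"dp_Pa": dp}
    for i in COMPARTMENTS:
        data[f"A{i}_mm2"] = np.asarray(area(i, dp))
        data[f"C{i}_mm2_per_Pa"] = np.asarray(distensibility(i, dp))
    df = pd.DataFrame(data)
    if path is not None:
        df.to_csv(path, index=False)
    return df
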