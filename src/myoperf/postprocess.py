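"""Derived hemodynamic quantities: microvascular flows, MBF maps, diameters.

The primary outputs of a converged cycle are

* the inter-compartment flow densities (per unit tissue volume, s⁻¹)
      arteriolar flow = β₁,₂ (p₁ − p₂),      capillary flow = β₂,₃ (p₂ − p₃),
  with the conductances evaluated at the same frozen state convention as the
  solver (previous time level);
* the myocardial blood flow map, MBF = time-averaged capillary flow converted
  to ml·min⁻¹ per 100 g of tissue;
* arteriolar/capillary diameters d_i = 2√(A_i/π) from the constitutive laws;
* morphology ratios of the total inflow waveform (systolic vs diastolic peaks
  and means) used to compare against Doppler flow measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constitutive as law
from .params import ParameterSet

ML_PER_S_TO_ML_PER_MIN = 60.0


def compartment_flows(p: np.ndarray, pim: np.ndarray, params: ParameterSet,
                      *, frozen_dp: np.ndarray | None = None):
    """Arteriolar and capillary flow densities (s⁻¹) from nodal pressures.

    ``frozen_dp`` (3, N) optionally supplies the transluminal pressures at
    which the conductances are evaluated (the solver's previous-level state);
    defaults to the current Δp.
    """
    dp = (p - pim[None, :]) if frozen_dp is None else frozen_dp
    b12 = np.asarray(law.exchange_conductance(1, 2, dp[0], dp[1], params))
    b23 = np.asarray(law.exchange_conductance(2, 3, dp[1], dp[2], params))
    return b12 * (p[0] - p[1]), b23 * (p[1] - p[2])


def capillary_flow_series(result) -> np.ndarray:
    """(S, N) capillary flow density over the stored cycle, s⁻¹.

    Conductances are frozen at the previous step's state, matching the
    semi-implicit solver; for rigid runs they are constants at Δp = 0.
    """
    S = len(result.times)
    out = np.empty((S, result.mesh.n_nodes))
    for s in range(S):
        prev = s - 1  # cyclic: step 0 uses the last step of the (periodic) cycle
        if result.rigid:
            dp = np.zeros_like(result.p_history[s])
        else:
            dp = result.p_history[prev] - result.pim_history[prev][None, :]
        _, cap = compartment_flows(result.p_history[s], result.pim_history[s],
                                   result.params, frozen_dp=dp)
        out[s] = cap
    return out


def arteriolar_flow_series(result) -> np.ndarray:
    S = len(result.times)
    out = np.empty((S, result.mesh.n_nodes))
    for s in range(S):
        prev = s - 1
        if result.rigid:
            dp = np.zeros_like(result.p_history[s])
        else:
            dp = result.p_history[prev] - result.pim_history[prev][None, :]
        art, _ = compartment_flows(result.p_history[s], result.pim_history[s],
                                   result.params, frozen_dp=dp)
        out[s] = art
    return out


@dataclass
class MBFMap:
    """Nodal myocardial blood flow with territory and global averages."""

    nodal: np.ndarray  # ml·min⁻¹·(100 g)⁻¹ per node
    territory_means: dict  # outlet id -> MBF
    global_mean: float

    def territory_variance(self) -> float:
        """Volume-unweighted variance of the per-territory means."""
        vals = np.array(list(self.territory_means.values()))
        return float(np.var(vals))


def flow_density_to_mbf(flow_density, tissue_density: float):
    """Convert a flow density (s⁻¹ ≡ ml blood/ml tissue/s) to ml/min/100 g."""
    return np.asarray(flow_density) * ML_PER_S_TO_ML_PER_MIN * 100.0 / tissue_density


def mbf_map(result) -> MBFMap:
    """Time-averaged capillary flow over the cycle as an MBF map."""
    cap = capillary_flow_series(result)  # (S, N)
    mean_flow = cap.mean(axis=0)  # uniform steps over one full period
    nodal = flow_density_to_mbf(mean_flow, result.params.tissue_density)
    nv = result.mesh.node_volumes
    tmap = result.tmap
    terr = {}
    for k in tmap.outlet_ids:
        m = tmap.label == k
        terr[k] = float(np.dot(nv[m], nodal[m]) / nv[m].sum())
    gmean = float(np.dot(nv, nodal) / nv.sum())
    return MBFMap(nodal=nodal, territory_means=terr, global_mean=gmean)


def diameters(p: np.ndarray, pim: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arteriolar and capillary diameters d_i = 2√(A_i/π) in μm."""
    dp = p - pim[None, :]
    d2 = 2.0 * np.sqrt(np.asarray(law.area(2, dp[1])) / np.pi) * 1e3
    d3 = 2.0 * np.sqrt(np.asarray(law.area(3, dp[2])) / np.pi) * 1e3
    return d2, d3


@dataclass
class FlowWaveforms:
    """Cycle-resolved flow series sharing one time grid."""

    times: np.ndarray  # s
    total_inflow: np.ndarray  # ml/min
    venous_outflow: np.ndarray  # ml/min
    systolic_window: tuple  # (t_on, t_off) s
    samples: dict | None = None  # depth label -> dict of series


def sample_point_nodes(mesh, depths_mm, thickness_from_lambda=True,
                       ray_origin=None) -> dict:
    """Nodes nearest to requested transmural depths (mm below epicardium).

    Depth is interpreted through λ: a depth of d mm in a wall of thickness L
    corresponds to λ = 1 − d/L.  ``ray_origin`` optionally restricts the
    search to nodes near a line through the wall (x, y of the origin).
    """
    lam = mesh.require_transmural()
    # wall thickness estimated from the λ gradient support: use bounding range
    zspan = mesh.nodes[:, 2].max() - mesh.nodes[:, 2].min()
    nodes = {}
    for name, d in depths_mm.items():
        target = 1.0 - d / zspan if d is not None else 0.5
        score = np.abs(lam - target)
        if ray_origin is not None:
            xy = np.linalg.norm(mesh.nodes[:, :2] - np.asarray(ray_origin)[:2],
                                axis=1)
            if xy.min() > np.sqrt(mesh.total_volume ** (2 / 3)):
                raise ValueError("sampling ray misses the domain")
            score = score + xy / max(xy.max(), 1e-300)
        nodes[name] = int(np.argmin(score))
    return nodes


def sample_waveforms(result, depths_mm=None, ray_origin=None) -> FlowWaveforms:
    """Arteriolar/capillary flow and diameter traces at transmural depths.

    Default depths: subendocardium and subepicardium 1 mm inside their
    surfaces, mid-wall midway (labels 'subendo', 'mid', 'subepi').
    """
    mesh = result.mesh
    zspan = mesh.nodes[:, 2].max() - mesh.nodes[:, 2].min()
    if depths_mm is None:
        depths_mm = {"subendo": zspan - 1.0, "mid": zspan / 2.0, "subepi": 1.0}
    picks = sample_point_nodes(mesh, depths_mm, ray_origin=ray_origin)
    art = arteriolar_flow_series(result)
    cap = capillary_flow_series(result)
    samples = {}
    for name, nid in picks.items():
        d2 = np.empty(len(result.times))
        d3 = np.empty(len(result.times))
        for s in range(len(result.times)):
            dd2, dd3 = diameters(result.p_history[s][:, [nid]],
                                 result.pim_history[s][[nid]])
            d2[s], d3[s] = dd2[0], dd3[0]
        samples[name] = {
            "node": nid,
            "arteriolar_flow": art[:, nid],
            "capillary_flow": cap[:, nid],
            "d2_um": d2,
            "d3_um": d3,
        }
    inflow = result.total_inflow * 1e6 * ML_PER_S_TO_ML_PER_MIN  # m³/s → ml/min
    outflow = result.venous_outflow_series * 1e6 * ML_PER_S_TO_ML_PER_MIN
    return FlowWaveforms(times=result.times, total_inflow=inflow,
                         venous_outflow=outflow,
                         systolic_window=result.systolic_window,
                         samples=samples)


def systolic_mask(times: np.ndarray, window: tuple) -> np.ndarray:
    t_on, t_off = window
    if t_off <= t_on:
        raise ValueError(f"empty systolic window {window}")
    return (times >= t_on) & (times <= t_off)


def flow_ratios(times: np.ndarray, inflow: np.ndarray, window: tuple) -> dict:
    """Morphology ratios of an inflow waveform over one cycle.

    Returns systolic/diastolic peak and mean ratios plus mean/peak within
    each phase, as used for comparison with Doppler-derived indices.
    """
    sys_m = systolic_mask(times, window)
    dia_m = ~sys_m
    if not sys_m.any() or not dia_m.any():
        raise ValueError("systolic window leaves one phase empty")
    qs, qd = inflow[sys_m], inflow[dia_m]
    return {
        "sys_dia_peak_ratio": float(qs.max() / qd.max()),
        "sys_dia_mean_ratio": float(qs.mean() / qd.mean()),
        "mean_peak_systole": float(qs.mean() / qs.max()),
        "mean_peak_diastole": float(qd.mean() / qd.max()),
    }
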