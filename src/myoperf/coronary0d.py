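"""Reduced (0D) epicardial coronary model coupled to the porous wall.

The full 3D epicardial hemodynamics is replaced by one lumped branch per
outlet: the flow through outlet k is driven by the gap between the inlet
(aortic) pressure and the volume-averaged first-compartment pressure of its
perfusion territory, through the coupling conductance α in series with an
optional epicardial path resistance R_k:

    q_k = (P_in(t) − ⟨p₁⟩_{Ω^k}) / (R_k + 1/α)        [m³·s⁻¹]

Retrograde (negative) flow is admissible.  Mass is handed to the porous
medium as the piecewise-constant source θ₁ = Σ_k χ^k q_k/|Ω^k| and drained
by the venous sink θ₃ = −γ(p₃ − p_ra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .driving import PressureWaveform
from .params import ParameterSet
from .territories import TerritoryMap

MM3_TO_M3 = 1e-9


@dataclass
class OutletNetwork:
    """Per-outlet lumped epicardial branches sharing one inlet waveform."""

    outlets: list
    coupling_conductance: float  # α, m³·s⁻¹·Pa⁻¹
    inlet_waveform: PressureWaveform
    flows: np.ndarray = field(default=None)  # q_k at the current step, m³/s

    def __post_init__(self):
        if self.coupling_conductance <= 0:
            raise ValueError("coupling conductance α must be positive")
        ids = [o.id for o in self.outlets]
        if len(set(ids)) != len(ids):
            raise ValueError("outlet ids must be unique")
        self.outlet_ids = tuple(sorted(ids))
        if self.flows is None:
            self.flows = np.zeros(len(self.outlets))

    def series_resistance(self) -> np.ndarray:
        """R_k + 1/α per outlet (sorted by id), Pa·s·m⁻³."""
        by_id = {o.id: o for o in self.outlets}
        return np.array([by_id[k].resistance + 1.0 / self.coupling_conductance
                         for k in self.outlet_ids])


def territory_mean_p1(p1: np.ndarray, tmap: TerritoryMap, mesh, k) -> float:
    """Volume-weighted mean of p₁ over territory Ω^k, Pa."""
    mask = tmap.label == k
    if not np.any(mask):
        raise ValueError(f"territory {k} is empty")
    w = mesh.node_volumes[mask]
    return float(np.dot(w, p1[mask]) / w.sum())


def all_territory_means(p1: np.ndarray, tmap: TerritoryMap, mesh) -> np.ndarray:
    """⟨p₁⟩ per territory, ordered by outlet id."""
    return np.array([territory_mean_p1(p1, tmap, mesh, k) for k in tmap.outlet_ids])


def outlet_flow(network: OutletNetwork, t: float, mean_p1: np.ndarray) -> np.ndarray:
    """Flows q_k = (P_in(t) − ⟨p₁⟩_k)/(R_k + 1/α) for all outlets, m³/s."""
    p_in = network.inlet_waveform(t)
    return (p_in - np.asarray(mean_p1, float)) / network.series_resistance()


def theta1_source(flows: np.ndarray, tmap: TerritoryMap, mesh) -> np.ndarray:
    """Nodal mass source θ₁ = Σ_k χ^k q_k/|Ω^k| in s⁻¹.

    The lumped volume integral of the result equals Σ_k q_k exactly.
    """
    theta = np.zeros(mesh.n_nodes)
    for q, k in zip(np.asarray(flows, float), tmap.outlet_ids):
        vol_m3 = tmap.volumes[k] * MM3_TO_M3
        if vol_m3 <= 0:
            raise ValueError(f"territory {k} has zero volume")
        theta[tmap.label == k] = q / vol_m3
    return theta


def theta3_sink(p3: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Venous sink θ₃ = −γ(p₃ − p_ra) in s⁻¹ (negative for outflow)."""
    return -params.venous_conductance * (np.asarray(p3, float)
                                         - params.right_atrium_pressure)


def venous_outflow(p3: np.ndarray, params: ParameterSet, mesh) -> float:
    """Total venous outflow −∫_Ω θ₃ dV in m³/s (lumped quadrature)."""
    return float(np.dot(mesh.node_volumes * MM3_TO_M3,
                        -theta3_sink(p3, params)))
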