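"""Physical and numerical parameters of the perfusion model.

All pressures are stored internally in Pa (1 mmHg = 133.322 Pa).  Length
densities and morphometry factors are kept in the mm-based units in which the
constitutive laws are written (areas in mm², length densities in mm·mm⁻³ ≡
mm⁻²); the specific permeability κ carries m² so that the Darcy permeabilities
K_i = (κ/μ)·φ_i come out in m²·Pa⁻¹·s⁻¹ directly.

Unit notes
----------
The published parameter table labels κ with m⁻¹, δ_i with mm⁻¹·s⁻¹·Pa⁻¹, γ
with s⁻¹ and the distensibilities with mmHg·Pa⁻¹.  None of those labels is
dimensionally consistent with the governing equations; we keep the printed
numeric values and assign the corrected units (κ: m², δ_i: mm⁻²·s⁻¹·Pa⁻¹,
γ: Pa⁻¹·s⁻¹, C_i: mm²·Pa⁻¹).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

MMHG_TO_PA = 133.322

#: fields that are pressures: stored in Pa, accepted in mmHg via `<name>_mmHg`
_PRESSURE_FIELDS = ("right_atrium_pressure", "peak_pressure")

#: per-compartment array fields (exactly 3 entries)
_ARRAY_FIELDS = ("length_density", "morphometry_factor")


def mmhg_to_pa(p):
    """Convert pressure from mmHg to Pa."""
    return np.asarray(p, dtype=float) * MMHG_TO_PA


def pa_to_mmhg(p):
    """Convert pressure from Pa to mmHg."""
    return np.asarray(p, dtype=float) / MMHG_TO_PA


@dataclass(frozen=True)
class ParameterSet:
    """All scalar and per-compartment constants of the model.

    Defaults are the published simulation values for the hyperemic state
    (patient-P1 personalization: peak brachial pressure 140 mmHg, stress
    period 0.714 s).  The compartment ordering is (1) small arteries,
    (2) arterioles, (3) capillaries.
    """

    #: vessel length density (nL)_i, mm·mm⁻³ (≡ mm⁻²)
    length_density: tuple = (0.5, 15.0, 8000.0)
    #: specific permeability κ of the fluid/matrix system, m²
    specific_permeability: float = 1.75e-10
    #: outlet coupling conductance α, m³·s⁻¹·Pa⁻¹
    coupling_conductance: float = 3e-10
    #: morphometry factor δ_i, mm⁻²·s⁻¹·Pa⁻¹
    morphometry_factor: tuple = (0.005, 0.05, 10.0)
    #: venous-return conductance γ, Pa⁻¹·s⁻¹
    venous_conductance: float = 8e-6
    #: right atrium pressure p_ra, Pa
    right_atrium_pressure: float = 2.0 * MMHG_TO_PA
    #: blood density ρ, kg·m⁻³ (unused by the 0D outlet surrogate)
    blood_density: float = 1063.0
    #: blood dynamic viscosity μ, Pa·s
    blood_viscosity: float = 0.0035
    #: peak (systolic) driving pressure, Pa
    peak_pressure: float = 140.0 * MMHG_TO_PA
    #: heartbeat period T, s
    period: float = 0.714
    #: fraction of the period occupied by systole
    systolic_fraction: float = 0.37
    #: time step Δt, s
    dt: float = 2e-3
    #: target Darcy mesh size h, mm
    mesh_size: float = 1.5
    #: fixed-point stopping tolerance ε on normalized diffs
    fp_tolerance: float = 1e-10
    #: fixed-point relaxation factor η
    relaxation: float = 0.1
    #: tissue density for MBF normalization, g·ml⁻¹
    tissue_density: float = 1.05

    def __post_init__(self):
        for name in _ARRAY_FIELDS:
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    # -- convenience views -------------------------------------------------
    @property
    def nL(self) -> np.ndarray:
        """(nL)_i as an array, mm⁻²."""
        return np.asarray(self.length_density)

    @property
    def delta(self) -> np.ndarray:
        """δ_i as an array, mm⁻²·s⁻¹·Pa⁻¹."""
        return np.asarray(self.morphometry_factor)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.to_dict().items()}
        return yaml.safe_dump(d, sort_keys=False)


_FIELD_NAMES = {f.name for f in fields(ParameterSet)}


def _check_positive(violations, name, value):
    if not np.all(np.isfinite(value)) or not np.all(np.asarray(value) > 0):
        violations.append(f"{name} = {value!r}: must be strictly positive and finite")


def validate_parameters(p: ParameterSet) -> list[str]:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    v: list[str] = []
    for name in _ARRAY_FIELDS:
        arr = np.atleast_1d(np.asarray(getattr(p, name), dtype=float))
        if arr.shape != (3,):
            v.append(f"{name} = {arr.tolist()}: needs exactly 3 per-compartment entries")
            continue
        _check_positive(v, name, arr)
    for name in (
        "specific_permeability", "coupling_conductance", "venous_conductance",
        "blood_density", "blood_viscosity", "peak_pressure", "period", "dt",
        "mesh_size", "fp_tolerance", "tissue_density",
    ):
        _check_positive(v, name, getattr(p, name))
    if not (0 < p.relaxation <= 1):
        v.append(f"relaxation = {p.relaxation}: must satisfy 0 < η ≤ 1")
    if not (0 < p.systolic_fraction < 1):
        v.append(f"systolic_fraction = {p.systolic_fraction}: must lie in (0, 1)")
    if not np.isfinite(p.right_atrium_pressure) or p.right_atrium_pressure < 0:
        v.append(f"right_atrium_pressure = {p.right_atrium_pressure}: must be ≥ 0")
    return v


def load_parameters(config=None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a flat key-value document.

    ``config`` may be a mapping, a YAML string, a path, or an open file.
    Missing keys fall back to the published defaults.  Pressure fields are
    stored in Pa; a key suffixed ``_mmHg`` supplies the value in mmHg instead.
    Unknown keys raise ``KeyError``.
    """
    if config is None:
        return ParameterSet()
    if isinstance(config, dict):
        doc = dict(config)
    else:
        if isinstance(config, (str, bytes)) and "\n" not in str(config) and ":" not in str(config):
            with open(config) as fh:
                doc = yaml.safe_load(fh)
        elif isinstance(config, io.IOBase) or hasattr(config, "read"):
            doc = yaml.safe_load(config)
        else:
            doc = yaml.safe_load(config)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError("configuration must be a flat key-value document")

    kw: dict = {}
    for key, value in doc.items():
        name = key
        if key.endswith("_mmHg"):
            name = key[: -len("_mmHg")]
            if name not in _PRESSURE_FIELDS:
                raise KeyError(f"unknown configuration key: {key!r}")
            value = float(value) * MMHG_TO_PA
        if name not in _FIELD_NAMES:
            raise KeyError(f"unknown configuration key: {key!r}")
        if name in kw:
            raise KeyError(f"duplicate configuration key: {key!r}")
        if name in _ARRAY_FIELDS:
            kw[name] = tuple(float(v) for v in value)
        else:
            kw[name] = float(value)
    pset = ParameterSet(**kw)
    violations = validate_parameters(pset)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    return pset
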