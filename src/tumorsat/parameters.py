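"""Domain types, unit conversion, and the built-in therapeutic-agent registry.

Every quantity is stored internally in SI units (metres, seconds, mol/L for
concentrations, cells/L for cell density).  The registry file shipped with the
package uses the units clinicians and package inserts use (hours, micromolar,
receptors per cell); conversion happens once, on load.

The registry holds one record per agent configuration: five FDA-approved solid
tumor antibody-drug conjugates (Enhertu appearing twice, for IHC 3+ and IHC 2+
HER2 expression), mirvetuximab soravtansine, and six approved PD-1/PD-L1
checkpoint inhibitors, each with its package-insert dose, peak and trough
plasma concentration, target expression, and internalization half-life.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import yaml

__all__ = [
    "AVOGADRO",
    "HOUR",
    "DEFAULT_BODY_WEIGHT_KG",
    "DEFAULT_PLASMA_VOLUME_L_PER_KG",
    "DEFAULT_CELL_DENSITY_PER_L",
    "InvalidParameterError",
    "AgentClass",
    "DoseBasis",
    "TargetProfile",
    "ExposureProfile",
    "TumorPhysiology",
    "AgentRecord",
    "default_physiology",
    "rate_constant_from_half_life",
    "half_life_from_rate_constant",
    "antigen_concentration",
    "cmax_from_dose",
    "load_registry",
    "registry_by_name",
    "dump_registry",
]

# ---------------------------------------------------------------------------
# Constants and configuration defaults
# ---------------------------------------------------------------------------

AVOGADRO = 6.02214076e23  # 1/mol
HOUR = 3600.0  # s

#: Reference body weight used to convert flat (mg) doses to plasma
#: concentration.  70 kg is the conventional adult reference.
DEFAULT_BODY_WEIGHT_KG = 70.0

#: Plasma volume per body weight (L/kg) for dose -> C_max conversion.
DEFAULT_PLASMA_VOLUME_L_PER_KG = 0.04

#: Tumor cell density, cells per litre of whole tumor (3e8 cells/mL), a
#: standard solid-tumor estimate used to turn receptors/cell into a molar
#: antigen concentration.
DEFAULT_CELL_DENSITY_PER_L = 3.0e11

#: Antibody molecular-weight sanity band (g/mol) for whole IgG and ADCs.
_MW_WARN_RANGE = (1.0e5, 1.6e5)


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain invariant."""


class AgentClass(str, Enum):
    ADC = "adc"
    CHECKPOINT_PD1 = "checkpoint_pd1"
    CHECKPOINT_PDL1 = "checkpoint_pdl1"
    #: virtual agents from the synthetic-cohort generator
    SYNTHETIC = "synthetic"


class DoseBasis(str, Enum):
    PER_KG = "per_kg"
    FLAT = "flat"


# ---------------------------------------------------------------------------
# Validated record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetProfile:
    """Cell-surface target of a therapeutic antibody.

    Parameters
    ----------
    target_name
        Antigen name (e.g. "HER2", "PD-1").
    receptors_per_cell
        Surface receptor copy number per cell (> 0).
    internalization_half_life
        Net internalization half-life in **seconds** (> 0); recycling is
        folded into this net rate.
    dissociation_constant
        Equilibrium K_d in mol/L; optional, only needed for the low-affinity
        Thiele variant.
    expressing_cell_fraction
        Fraction of tumor cells expressing the target, in (0, 1].  Defaults
        to 1, i.e. receptors/cell is treated as a tumor-average value.
    """

    target_name: str
    receptors_per_cell: float
    internalization_half_life: float
    dissociation_constant: Optional[float] = None
    expressing_cell_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.receptors_per_cell > 0:
            raise InvalidParameterError(
                f"receptors_per_cell must be > 0, got {self.receptors_per_cell}"
            )
        if not self.internalization_half_life > 0:
            raise InvalidParameterError(
                "internalization_half_life must be > 0, got "
                f"{self.internalization_half_life}"
            )
        if not (0.0 < self.expressing_cell_fraction <= 1.0):
            raise InvalidParameterError(
                "expressing_cell_fraction must be in (0, 1], got "
                f"{self.expressing_cell_fraction}"
            )
        if self.dissociation_constant is not None and self.dissociation_constant < 0:
            raise InvalidParameterError("dissociation_constant must be >= 0")


@dataclass(frozen=True)
class ExposureProfile:
    """Clinical exposure of an agent: dose and plasma concentration window.

    c_max/c_trough are in mol/L; dose_amount is mg (flat) or mg/kg (per_kg).
    """

    dose_amount: float
    dose_basis: DoseBasis
    schedule_text: str
    molecular_weight: float  # g/mol
    c_max: Optional[float] = None
    c_trough: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dose_amount < 0:
            raise InvalidParameterError("dose_amount must be >= 0")
        if self.molecular_weight <= 0:
            raise InvalidParameterError("molecular_weight must be > 0")
        if self.c_max is not None and self.c_max < 0:
            raise InvalidParameterError("c_max must be >= 0")
        if self.c_trough is not None:
            if self.c_trough < 0:
                raise InvalidParameterError("c_trough must be >= 0")
            if self.c_max is not None and self.c_max < self.c_trough:
                raise InvalidParameterError(
                    f"c_max ({self.c_max}) must be >= c_trough ({self.c_trough})"
                )
        lo, hi = _MW_WARN_RANGE
        if not (lo <= self.molecular_weight <= hi):
            warnings.warn(
                f"molecular_weight {self.molecular_weight:g} g/mol is outside the "
                f"whole-antibody range [{lo:g}, {hi:g}]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TumorPhysiology:
    """Krogh-cylinder vascular and tissue parameters (SI units).

    The Krogh cylinder is an annulus of tissue of outer radius ``krogh_radius``
    supplied by a central capillary of radius ``capillary_radius``.  Vascular
    exchange can be specified either as a permeability ``permeability`` (m/s)
    or directly as the lumped delivery rate constant ``ps_over_v`` (1/s);
    the two are related through the vessel surface-to-volume ratio
    S/V = 2*R_cap/R_Krogh**2.
    """

    capillary_radius: float = 8.0e-6  # m
    krogh_radius: float = 75.0e-6  # m
    void_fraction: float = 0.24
    diffusivity: float = 1.0e-11  # m^2/s (~10 um^2/s, typical IgG in tumor)
    permeability: Optional[float] = None  # m/s
    ps_over_v: Optional[float] = 6.0e-6  # 1/s
    cell_density: float = DEFAULT_CELL_DENSITY_PER_L  # cells per L tumor

    def __post_init__(self) -> None:
        if not self.capillary_radius > 0:
            raise InvalidParameterError("capillary_radius must be > 0")
        if not self.krogh_radius > self.capillary_radius:
            raise InvalidParameterError(
                f"krogh_radius ({self.krogh_radius}) must exceed capillary_radius "
                f"({self.capillary_radius})"
            )
        if not (0.0 < self.void_fraction < 1.0):
            raise InvalidParameterError("void_fraction must be in (0, 1)")
        if not self.diffusivity > 0:
            raise InvalidParameterError("diffusivity must be > 0")
        if not self.cell_density > 0:
            raise InvalidParameterError("cell_density must be > 0")
        if self.permeability is None and self.ps_over_v is None:
            raise InvalidParameterError(
                "at least one of permeability and ps_over_v must be given"
            )
        for name in ("permeability", "ps_over_v"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidParameterError(f"{name} must be > 0 when given")
        if self.permeability is not None and self.ps_over_v is not None:
            implied = self.permeability * self._sv()
            if abs(implied - self.ps_over_v) > 0.01 * self.ps_over_v:
                raise InvalidParameterError(
                    f"permeability and ps_over_v are inconsistent: P*(S/V) = "
                    f"{implied:.4g} /s vs ps_over_v = {self.ps_over_v:.4g} /s"
                )

    def _sv(self) -> float:
        """Vessel surface area per tumor volume, 2*R_cap/R_Krogh**2 (1/m)."""
        return 2.0 * self.capillary_radius / self.krogh_radius**2

    def resolved_permeability(self) -> float:
        """Capillary permeability P (m/s), derived from PS/V if not given."""
        if self.permeability is not None:
            return self.permeability
        assert self.ps_over_v is not None
        return self.ps_over_v / self._sv()

    def resolved_ps_over_v(self) -> float:
        """Lumped delivery rate constant PS/V (1/s)."""
        if self.ps_over_v is not None:
            return self.ps_over_v
        assert self.permeability is not None
        return self.permeability * self._sv()


@dataclass(frozen=True)
class AgentRecord:
    """One therapeutic agent configuration: target, exposure, provenance."""

    name: str
    agent_class: AgentClass
    target: TargetProfile
    exposure: ExposureProfile
    ps_over_v: Optional[float] = None  # 1/s, per-agent tabulated value
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidParameterError("agent name must be non-empty")
        if self.ps_over_v is not None and self.ps_over_v <= 0:
            raise InvalidParameterError("ps_over_v must be > 0 when given")


def default_physiology(**overrides) -> TumorPhysiology:
    """Default Krogh-cylinder physiology (see class docstring for values)."""
    return TumorPhysiology(**overrides)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def rate_constant_from_half_life(half_life: float) -> float:
    """First-order rate constant (1/s) from a half-life in seconds.

    k = ln(2) / t_half.  Used to turn the tabulated internalization
    half-lives into the endocytic consumption rate k_e.
    """
    if not half_life > 0:
        raise InvalidParameterError(f"half_life must be > 0, got {half_life}")
    return math.log(2.0) / half_life


def half_life_from_rate_constant(rate: float) -> float:
    """Inverse of :func:`rate_constant_from_half_life`."""
    if not rate > 0:
        raise InvalidParameterError(f"rate must be > 0, got {rate}")
    return math.log(2.0) / rate


def antigen_concentration(
    target: TargetProfile, physiology: TumorPhysiology
) -> float:
    """Available antigen concentration [Ag] in mol per litre of whole tumor.

    receptors/cell x expressing cell fraction x cells/L / N_A.
    """
    return (
        target.receptors_per_cell
        * target.expressing_cell_fraction
        * physiology.cell_density
        / AVOGADRO
    )


def cmax_from_dose(
    exposure: ExposureProfile,
    body_weight: float = DEFAULT_BODY_WEIGHT_KG,
    plasma_volume_per_kg: float = DEFAULT_PLASMA_VOLUME_L_PER_KG,
) -> float:
    """Estimate peak plasma concentration (mol/L) from the administered dose.

    A single-compartment estimate: the full dose is assumed to distribute
    instantaneously into plasma (``plasma_volume_per_kg`` L/kg).  This is
    plumbing for registry entries that lack a measured C_max; tabulated
    C_max values are always preferred when present.
    """
    if plasma_volume_per_kg <= 0:
        raise InvalidParameterError("plasma_volume_per_kg must be > 0")
    mg_per_kg: float
    if exposure.dose_basis is DoseBasis.PER_KG:
        mg_per_kg = exposure.dose_amount
    else:
        if body_weight is None or body_weight <= 0:
            raise InvalidParameterError(
                "flat doses require a positive body_weight"
            )
        mg_per_kg = exposure.dose_amount / body_weight
    grams_per_l = mg_per_kg * 1e-3 / plasma_volume_per_kg
    return grams_per_l / exposure.molecular_weight


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

_REGISTRY_RESOURCE = "registry.yaml"


def _record_from_dict(d: dict) -> AgentRecord:
    t = d["target"]
    kd = t.get("dissociation_constant_nM")
    target = TargetProfile(
        target_name=t["target_name"],
        receptors_per_cell=float(t["receptors_per_cell"]),
        internalization_half_life=float(t["internalization_half_life_h"]) * HOUR,
        dissociation_constant=None if kd is None else float(kd) * 1e-9,
        expressing_cell_fraction=float(t.get("expressing_cell_fraction", 1.0)),
    )
    e = d["exposure"]
    c_max = e.get("c_max_uM")
    c_trough = e.get("c_trough_uM")
    exposure = ExposureProfile(
        dose_amount=float(e["dose_amount"]),
        dose_basis=DoseBasis(e["dose_basis"]),
        schedule_text=str(e["schedule_text"]),
        molecular_weight=float(e["molecular_weight_g_mol"]),
        c_max=None if c_max is None else float(c_max) * 1e-6,
        c_trough=None if c_trough is None else float(c_trough) * 1e-6,
    )
    psv = d.get("ps_over_v_per_s")
    return AgentRecord(
        name=str(d["name"]),
        agent_class=AgentClass(d["agent_class"]),
        target=target,
        exposure=exposure,
        ps_over_v=None if psv is None else float(psv),
        provenance=tuple(d.get("provenance", ())),
    )


def _record_to_dict(r: AgentRecord) -> dict:
    t = r.target
    e = r.exposure
    d: dict = {
        "name": r.name,
        "agent_class": r.agent_class.value,
        "target": {
            "target_name": t.target_name,
            "receptors_per_cell": t.receptors_per_cell,
            "internalization_half_life_h": t.internalization_half_life / HOUR,
        },
        "exposure": {
            "dose_amount": e.dose_amount,
            "dose_basis": e.dose_basis.value,
            "schedule_text": e.schedule_text,
            "molecular_weight_g_mol": e.molecular_weight,
        },
    }
    if t.dissociation_constant is not None:
        d["target"]["dissociation_constant_nM"] = t.dissociation_constant / 1e-9
    if t.expressing_cell_fraction != 1.0:
        d["target"]["expressing_cell_fraction"] = t.expressing_cell_fraction
    if e.c_max is not None:
        d["exposure"]["c_max_uM"] = e.c_max / 1e-6
    if e.c_trough is not None:
        d["exposure"]["c_trough_uM"] = e.c_trough / 1e-6
    if r.ps_over_v is not None:
        d["ps_over_v_per_s"] = r.ps_over_v
    if r.provenance:
        d["provenance"] = list(r.provenance)
    return d


def load_registry(path: Optional[str] = None) -> list[AgentRecord]:
    """Load the agent registry (the packaged file by default).

    Returns the 13 built-in agent configurations, in file order.  Duplicate
    names are rejected.
    """
    if path is None:
        text = (
            resources.files("tumorsat").joinpath(f"data/{_REGISTRY_RESOURCE}")
        ).read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    records = [_record_from_dict(d) for d in raw["agents"]]
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise InvalidParameterError("duplicate agent names in registry")
    return records


def registry_by_name(records: Sequence[AgentRecord]) -> dict[str, AgentRecord]:
    return {r.name: r for r in records}


def dump_registry(records: Sequence[AgentRecord], path: str) -> None:
    """Write records back to the registry text format (lossless round-trip)."""
    doc = {"agents": [_record_to_dict(r) for r in records]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def with_registry_ps_over_v(
    agent: AgentRecord, physiology: TumorPhysiology
) -> TumorPhysiology:
    """Return physiology with the agent's tabulated PS/V substituted in."""
    if agent.ps_over_v is None:
        return physiology
    return replace(physiology, ps_over_v=agent.ps_over_v, permeability=None)
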