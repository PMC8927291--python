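"""Synthetic virtual-agent cohorts spanning the saturation regimes.

The generator draws virtual agent/tumor parameter sets (internalization
half-life, receptor expression, peak plasma concentration, trough ratio,
jittered vascular delivery and cell density) log-uniformly over ranges that
bracket the clinical envelope of approved ADCs and checkpoint inhibitors:
half-lives 3.7-36 h, expression 5,600-1,000,000 receptors/cell, C_max
0.28-2.97 uM, each extended threefold on both sides.  Every agent carries
its analytic squared Thiele modulus as ground truth, and can additionally
be labelled with the steady-state saturated fraction from the mechanistic
Krogh simulator, enabling concordance analysis between the analytic
classifier and the PDE oracle without any external data.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .krogh import KroghConfig, SolverError, steady_state_saturation
from .parameters import (
    AgentClass,
    AgentRecord,
    DoseBasis,
    ExposureProfile,
    InvalidParameterError,
    TargetProfile,
    TumorPhysiology,
    antigen_concentration,
    default_physiology,
    rate_constant_from_half_life,
)
from .thiele import thiele_squared_low_affinity, thiele_squared_simplified

__all__ = [
    "BAND_LOW",
    "BAND_HIGH",
    "CohortSpec",
    "SyntheticAgent",
    "ConcordanceReport",
    "generate",
    "label_with_oracle",
    "concordance_report",
    "cohort_to_csv",
]

#: phi^2 bands for concordance analysis: < BAND_LOW should saturate,
#: > BAND_HIGH should not; in between is the excluded boundary band.
BAND_LOW = 0.3
BAND_HIGH = 3.0

_HOUR = 3600.0


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a synthetic cohort.

    Ranges are (low, high) with low < high; half-life in hours, C_max in
    mol/L.  ``physiology_jitter`` is a multiplicative log-uniform spread
    factor applied independently to PS/V and cell density.
    """

    n_agents: int
    seed: int
    half_life_range_h: tuple[float, float] = (3.7 / 3.0, 36.0 * 3.0)
    receptors_range: tuple[float, float] = (5600.0 / 3.0, 1.0e6 * 3.0)
    cmax_range_m: tuple[float, float] = (0.284e-6 / 3.0, 2.97e-6 * 3.0)
    trough_ratio_range: tuple[float, float] = (0.02, 0.7)
    physiology_jitter: float = 1.5
    include_low_affinity: bool = False
    kd_range_m: tuple[float, float] = (1.0e-10, 1.0e-6)

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise InvalidParameterError("n_agents must be >= 1")
        for name in (
            "half_life_range_h",
            "receptors_range",
            "cmax_range_m",
            "trough_ratio_range",
            "kd_range_m",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise InvalidParameterError(
                    f"{name} must satisfy 0 < low < high, got ({lo}, {hi})"
                )
        if self.physiology_jitter < 1.0:
            raise InvalidParameterError("physiology_jitter must be >= 1")

    def content_hash(self) -> str:
        doc = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "n_agents": self.n_agents,
            "seed": self.seed,
            "half_life_range_h": list(self.half_life_range_h),
            "receptors_range": list(self.receptors_range),
            "cmax_range_m": list(self.cmax_range_m),
            "trough_ratio_range": list(self.trough_ratio_range),
            "physiology_jitter": self.physiology_jitter,
            "include_low_affinity": self.include_low_affinity,
            "kd_range_m": list(self.kd_range_m),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        kw = dict(d)
        for name in (
            "half_life_range_h",
            "receptors_range",
            "cmax_range_m",
            "trough_ratio_range",
            "kd_range_m",
        ):
            if name in kw:
                kw[name] = tuple(float(x) for x in kw[name])
        return cls(**kw)


@dataclass
class SyntheticAgent:
    """A virtual agent: record + its physiology + analytic ground truth."""

    record: AgentRecord
    physiology: TumorPhysiology
    true_phi2: float
    oracle_saturated_fraction: Optional[float] = None
    oracle_error: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.true_phi2 >= 0:
            raise InvalidParameterError("true_phi2 must be non-negative")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def generate(spec: CohortSpec) -> list[SyntheticAgent]:
    """Draw a cohort deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    base = default_physiology()
    agents: list[SyntheticAgent] = []
    for i in range(spec.n_agents):
        half_life = _log_uniform(rng, *spec.half_life_range_h) * _HOUR
        receptors = _log_uniform(rng, *spec.receptors_range)
        c_max = _log_uniform(rng, *spec.cmax_range_m)
        trough_ratio = float(rng.uniform(*spec.trough_ratio_range))
        j = spec.physiology_jitter
        psv = base.resolved_ps_over_v() * _log_uniform(rng, 1.0 / j, j)
        density = base.cell_density * _log_uniform(rng, 1.0 / j, j)
        kd = (
            _log_uniform(rng, *spec.kd_range_m)
            if spec.include_low_affinity
            else None
        )
        physiology = replace(
            base, ps_over_v=psv, permeability=None, cell_density=density
        )
        target = TargetProfile(
            target_name="synthetic antigen",
            receptors_per_cell=receptors,
            internalization_half_life=half_life,
            dissociation_constant=kd,
        )
        exposure = ExposureProfile(
            dose_amount=0.0,
            dose_basis=DoseBasis.FLAT,
            schedule_text="synthetic",
            molecular_weight=150000.0,
            c_max=c_max,
            c_trough=c_max * trough_ratio,
        )
        record = AgentRecord(
            name=f"virtual-{i:04d}",
            agent_class=AgentClass.SYNTHETIC,
            target=target,
            exposure=exposure,
            ps_over_v=psv,
            provenance=("synthetic cohort sample",),
        )
        k_e = rate_constant_from_half_life(half_life)
        ag = antigen_concentration(target, physiology)
        if kd is None:
            phi2 = thiele_squared_simplified(k_e, ag, psv, c_max)
        else:
            phi2 = thiele_squared_low_affinity(k_e, ag, psv, c_max, kd)
        agents.append(
            SyntheticAgent(
                record=record, physiology=physiology, true_phi2=phi2
            )
        )
    return agents


def label_with_oracle(
    cohort: Sequence[SyntheticAgent],
    sim_defaults: Optional[dict] = None,
) -> list[SyntheticAgent]:
    """Fill ``oracle_saturated_fraction`` by running the Krogh simulator.

    Each agent is simulated to steady state at its constant C_max forcing.
    Per-agent solver failures are recorded on the agent (``oracle_error``)
    rather than aborting the batch.  Input order is preserved; agents are
    modified in place and the same list is returned.
    """
    sim_defaults = dict(sim_defaults or {})
    out = list(cohort)
    for agent in out:
        target = agent.record.target
        kd = target.dissociation_constant
        kw = {
            "binding_on_rate": 1.0e5,
            "binding_off_rate": 1.0e5 * (kd if kd is not None else 1.0e-9),
            "radial_grid_points": 64,
        }
        kw.update(sim_defaults)
        config = KroghConfig(
            physiology=agent.physiology,
            internalization_rate=rate_constant_from_half_life(
                target.internalization_half_life
            ),
            antigen_total=antigen_concentration(target, agent.physiology),
            plasma_forcing=agent.record.exposure.c_max,
            **kw,
        )
        try:
            agent.oracle_saturated_fraction = steady_state_saturation(config)
            agent.oracle_error = None
        except SolverError as exc:  # pragma: no cover - defensive
            agent.oracle_saturated_fraction = None
            agent.oracle_error = str(exc)
    return out


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between the analytic phi^2 bands and the PDE oracle."""

    n_low: int  # phi^2 < BAND_LOW
    n_low_concordant: int  # ... with saturated fraction >= 0.9
    n_high: int  # phi^2 > BAND_HIGH
    n_high_concordant: int  # ... with saturated fraction < 0.9
    n_boundary: int  # BAND_LOW <= phi^2 <= BAND_HIGH (excluded)
    n_failed: int  # oracle did not produce a label

    @property
    def total(self) -> int:
        return self.n_low + self.n_high + self.n_boundary + self.n_failed

    @property
    def concordance_low(self) -> float:
        return self.n_low_concordant / self.n_low if self.n_low else float("nan")

    @property
    def concordance_high(self) -> float:
        return (
            self.n_high_concordant / self.n_high if self.n_high else float("nan")
        )

    def to_text(self) -> str:
        lines = [
            f"agents total:            {self.total}",
            f"phi2 < {BAND_LOW:g} (saturated): {self.n_low} "
            f"({self.n_low_concordant} concordant)",
            f"phi2 > {BAND_HIGH:g} (limited):   {self.n_high} "
            f"({self.n_high_concordant} concordant)",
            f"boundary band:           {self.n_boundary}",
            f"oracle failures:         {self.n_failed}",
        ]
        return "\n".join(lines) + "\n"


def concordance_report(cohort: Sequence[SyntheticAgent]) -> ConcordanceReport:
    """Partition a labelled cohort by phi^2 band and tabulate agreement."""
    n_low = n_low_c = n_high = n_high_c = n_boundary = n_failed = 0
    for agent in cohort:
        sat = agent.oracle_saturated_fraction
        if sat is None:
            if agent.oracle_error is None:
                raise InvalidParameterError(
                    f"agent {agent.record.name!r} has no oracle label; run "
                    "label_with_oracle first"
                )
            n_failed += 1
            continue
        phi2 = agent.true_phi2
        if phi2 < BAND_LOW:
            n_low += 1
            n_low_c += sat >= 0.9
        elif phi2 > BAND_HIGH:
            n_high += 1
            n_high_c += sat < 0.9
        else:
            n_boundary += 1
    return ConcordanceReport(
        n_low=n_low,
        n_low_concordant=n_low_c,
        n_high=n_high,
        n_high_concordant=n_high_c,
        n_boundary=n_boundary,
        n_failed=n_failed,
    )


def cohort_to_csv(cohort: Sequence[SyntheticAgent], spec: CohortSpec) -> str:
    """Cohort table as CSV text with a provenance header."""
    lines = [
        f"# tumorsat {_pkg_version} synthetic cohort",
        f"# seed={spec.seed} spec_hash={spec.content_hash()}",
        "name,half_life_h,receptors_per_cell,c_max_m,c_trough_m,"
        "ps_over_v_per_s,cell_density_per_l,kd_m,true_phi2,"
        "oracle_saturated_fraction,oracle_error",
    ]
    for a in cohort:
        t = a.record.target
        e = a.record.exposure
        kd = t.dissociation_constant
        sat = a.oracle_saturated_fraction
        lines.append(
            ",".join(
                [
                    a.record.name,
                    f"{t.internalization_half_life / _HOUR:.10g}",
                    f"{t.receptors_per_cell:.10g}",
                    f"{e.c_max:.10g}",
                    f"{e.c_trough:.10g}",
                    f"{a.physiology.resolved_ps_over_v():.10g}",
                    f"{a.physiology.cell_density:.10g}",
                    "" if kd is None else f"{kd:.10g}",
                    f"{a.true_phi2:.10g}",
                    "" if sat is None else f"{sat:.10g}",
                    "" if a.oracle_error is None else a.oracle_error.replace(",", ";"),
                ]
            )
        )
    return "\n".join(lines) + "\n"
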