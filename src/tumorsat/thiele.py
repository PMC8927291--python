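"""Thiele modulus and Biot number for antibody delivery to tumors.

The (squared) Thiele modulus compares the rate at which a tumor consumes
antibody by target-mediated internalization with the rate at which the
vasculature can deliver it:

    phi^2 = k_e * [Ag] / ((PS/V) * [Ab])          (permeability-limited form)

where k_e is the internalization rate constant, [Ag] the available antigen
concentration per tumor volume, PS/V the permeability-surface-area delivery
rate constant, and [Ab] the plasma antibody concentration.  phi^2 << 1 means
the dose supersaturates the target everywhere; phi^2 > 1 means consumption
outruns delivery and penetration is incomplete (the "binding-site barrier").

The full high-affinity form keeps the interstitial diffusion resistance
explicit through the Biot number Bi = 2*P*R_cap/(D*eps):

    phi^2 = k_e * R_Krogh^2 * ([Ag]/eps) * (1 + 1/Bi) / (D * [Ab])

and reduces to the permeability-limited form when Bi is small (the usual
antibody case: extravasation much slower than interstitial diffusion).  The
two forms differ exactly by a factor (1 + Bi).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .parameters import (
    AgentRecord,
    InvalidParameterError,
    TumorPhysiology,
    antigen_concentration,
    default_physiology,
    rate_constant_from_half_life,
    with_registry_ps_over_v,
)

__all__ = [
    "SUPERSATURATION_THRESHOLD",
    "PENETRATION_THRESHOLD",
    "Regime",
    "Formula",
    "ThieleResult",
    "surface_to_volume",
    "biot_number",
    "thiele_squared_simplified",
    "thiele_squared_full",
    "thiele_squared_low_affinity",
    "classify_regime",
    "evaluate_agent",
]

#: phi^2 below this leaves a 10-fold vascularization safety margin.
SUPERSATURATION_THRESHOLD = 0.1
#: phi^2 above this predicts incomplete penetration / unsaturated receptors.
PENETRATION_THRESHOLD = 1.0


class Regime(str, Enum):
    SUPERSATURATED = "supersaturated"
    SATURATING = "saturating"
    PENETRATION_LIMITED = "penetration_limited"


class Formula(str, Enum):
    SIMPLIFIED = "simplified"
    FULL = "full"


@dataclass(frozen=True)
class ThieleResult:
    """Squared Thiele modulus of one agent at its exposure window.

    ``phi2_ctrough`` is ``math.inf`` when the trough concentration is zero
    (no delivery at trough); reports render this as "unbounded".
    """

    agent_name: str
    phi2_cmax: float
    biot: float
    formula_used: Formula
    regime: Regime
    phi2_ctrough: Optional[float] = None
    inputs_echo: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (self.phi2_cmax >= 0):
            raise InvalidParameterError("phi2_cmax must be non-negative")
        if not (self.biot > 0):
            raise InvalidParameterError("biot must be positive")
        if self.phi2_ctrough is not None and not (
            self.phi2_ctrough >= self.phi2_cmax
        ):
            # phi^2 is inversely proportional to [Ab], so trough >= cmax
            raise InvalidParameterError(
                "phi2_ctrough must be >= phi2_cmax (trough concentration "
                "cannot exceed peak)"
            )


def surface_to_volume(physiology: TumorPhysiology) -> float:
    """Vessel surface per tumor volume for a Krogh cylinder (1/m).

    S/V = 2*R_cap/R_Krogh**2.
    """
    return 2.0 * physiology.capillary_radius / physiology.krogh_radius**2


def biot_number(physiology: TumorPhysiology) -> float:
    """Biot number Bi = 2*P*R_cap/(D*eps) (dimensionless).

    Ratio of trans-capillary transport to interstitial diffusion; small Bi
    means delivery is permeability-limited.  P is resolved from PS/V when
    not given directly.
    """
    p = physiology.resolved_permeability()
    return (
        2.0
        * p
        * physiology.capillary_radius
        / (physiology.diffusivity * physiology.void_fraction)
    )


def thiele_squared_simplified(
    k_e: float, antigen: float, ps_over_v: float, antibody_plasma: float
) -> float:
    """Permeability-limited squared Thiele modulus k_e*[Ag]/((PS/V)*[Ab]).

    Returns ``math.inf`` when the plasma concentration is zero (explicit
    "no delivery" outcome, not an overflow).
    """
    if k_e < 0 or antigen < 0:
        raise InvalidParameterError("k_e and antigen must be non-negative")
    if ps_over_v <= 0:
        raise InvalidParameterError("ps_over_v must be > 0")
    if antibody_plasma < 0:
        raise InvalidParameterError("antibody_plasma must be >= 0")
    if antibody_plasma == 0.0:
        return math.inf if k_e * antigen > 0 else 0.0
    return k_e * antigen / (ps_over_v * antibody_plasma)


def thiele_squared_full(
    k_e: float,
    antigen: float,
    physiology: TumorPhysiology,
    antibody_plasma: float,
) -> float:
    """Full high-affinity squared Thiele modulus.

    k_e * R_Krogh^2 * ([Ag]/eps) * (1 + 1/Bi) / (D * [Ab]).  Equals the
    simplified form times (1 + Bi); for small Bi (permeability-limited
    antibodies) the two agree.
    """
    if k_e < 0 or antigen < 0:
        raise InvalidParameterError("k_e and antigen must be non-negative")
    if antibody_plasma < 0:
        raise InvalidParameterError("antibody_plasma must be >= 0")
    if antibody_plasma == 0.0:
        return math.inf if k_e * antigen > 0 else 0.0
    bi = biot_number(physiology)
    return (
        k_e
        * physiology.krogh_radius**2
        * (antigen / physiology.void_fraction)
        * (1.0 + 1.0 / bi)
        / (physiology.diffusivity * antibody_plasma)
    )


def thiele_squared_low_affinity(
    k_e: float,
    antigen: float,
    ps_over_v: float,
    antibody_plasma: float,
    kd: float,
) -> float:
    """Saturable-sink Thiele variant for antibodies of finite affinity.

    When K_d is comparable to the plasma concentration, only the bound
    fraction of surface receptors is internalized at equilibrium, so the
    consumption term is scaled by [Ab]/([Ab] + K_d):

        phi^2_lowaff = phi^2_simplified * [Ab]/([Ab] + K_d)

    This reduces to the high-affinity form as K_d -> 0.  It is a documented
    package variant validated against the reaction-diffusion simulator, not
    a literature formula.
    """
    if kd < 0:
        raise InvalidParameterError("kd must be >= 0")
    base = thiele_squared_simplified(k_e, antigen, ps_over_v, antibody_plasma)
    if not math.isfinite(base):
        return base
    if antibody_plasma == 0.0:
        return base
    return base * antibody_plasma / (antibody_plasma + kd)


def classify_regime(phi2_cmax: float) -> Regime:
    """Saturation regime label from phi^2 at peak plasma concentration."""
    if phi2_cmax < SUPERSATURATION_THRESHOLD:
        return Regime.SUPERSATURATED
    if phi2_cmax <= PENETRATION_THRESHOLD:
        return Regime.SATURATING
    return Regime.PENETRATION_LIMITED


def evaluate_agent(
    agent: AgentRecord,
    physiology: Optional[TumorPhysiology] = None,
    formula: Formula | str = Formula.SIMPLIFIED,
) -> ThieleResult:
    """Compute the Thiele analysis for one registry agent.

    When ``physiology`` is omitted, the default Krogh physiology is used
    with the agent's tabulated PS/V substituted in.  phi^2 is evaluated at
    C_max (required) and at C_trough when present; a zero trough yields an
    infinite trough modulus.
    """
    formula = Formula(formula)
    if physiology is None:
        physiology = with_registry_ps_over_v(agent, default_physiology())
    if agent.exposure.c_max is None:
        raise InvalidParameterError(
            f"agent {agent.name!r} has no c_max; cannot evaluate"
        )
    k_e = rate_constant_from_half_life(agent.target.internalization_half_life)
    ag = antigen_concentration(agent.target, physiology)
    psv = physiology.resolved_ps_over_v()
    bi = biot_number(physiology)

    def phi2(ab: float) -> float:
        if formula is Formula.FULL:
            return thiele_squared_full(k_e, ag, physiology, ab)
        return thiele_squared_simplified(k_e, ag, psv, ab)

    phi2_cmax = phi2(agent.exposure.c_max)
    phi2_ctrough = (
        None
        if agent.exposure.c_trough is None
        else phi2(agent.exposure.c_trough)
    )
    return ThieleResult(
        agent_name=agent.name,
        phi2_cmax=phi2_cmax,
        phi2_ctrough=phi2_ctrough,
        biot=bi,
        formula_used=formula,
        regime=classify_regime(phi2_cmax),
        inputs_echo={
            "k_e_per_s": k_e,
            "antigen_m": ag,
            "ps_over_v_per_s": psv,
            "c_max_m": agent.exposure.c_max,
            "c_trough_m": agent.exposure.c_trough,
            "cell_density_per_l": physiology.cell_density,
        },
    )
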