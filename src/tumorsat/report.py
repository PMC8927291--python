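"""Per-agent saturation report: the tabular counterpart of the bar charts.

One row per registry agent with its squared Thiele modulus at C_max and
C_trough, Biot number, and regime label.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .parameters import AgentRecord, TumorPhysiology
from .thiele import Formula, ThieleResult, evaluate_agent

__all__ = ["ReportRow", "build_report", "report_frame", "format_value"]

_COLUMNS = [
    "name",
    "agent_class",
    "phi2_cmax",
    "phi2_ctrough",
    "biot",
    "regime",
    "provenance",
]


@dataclass(frozen=True)
class ReportRow:
    name: str
    agent_class: str
    phi2_cmax: float
    phi2_ctrough: Optional[float]
    biot: float
    regime: str
    provenance: str

    @classmethod
    def from_result(cls, agent: AgentRecord, res: ThieleResult) -> "ReportRow":
        return cls(
            name=agent.name,
            agent_class=agent.agent_class.value,
            phi2_cmax=res.phi2_cmax,
            phi2_ctrough=res.phi2_ctrough,
            biot=res.biot,
            regime=res.regime.value,
            provenance="; ".join(agent.provenance),
        )


def build_report(
    agents: Sequence[AgentRecord],
    physiology: Optional[TumorPhysiology] = None,
    formula: Formula | str = Formula.SIMPLIFIED,
) -> list[ReportRow]:
    """Evaluate every agent and return rows in registry order."""
    rows = []
    for agent in agents:
        res = evaluate_agent(agent, physiology=physiology, formula=formula)
        rows.append(ReportRow.from_result(agent, res))
    return rows


def format_value(x: Optional[float], precision: int = 3) -> str:
    """Render a phi^2 value: 3 significant figures, 'unbounded' for inf."""
    if x is None:
        return ""
    if math.isinf(x):
        return "unbounded"
    return f"{x:.{precision}g}"


def report_frame(
    rows: Sequence[ReportRow], precision: Optional[int] = 3
) -> pd.DataFrame:
    """Rows as a DataFrame; ``precision=None`` keeps full float precision."""
    recs = []
    for r in rows:
        rec = {
            "name": r.name,
            "agent_class": r.agent_class,
            "phi2_cmax": r.phi2_cmax,
            "phi2_ctrough": r.phi2_ctrough,
            "biot": r.biot,
            "regime": r.regime,
            "provenance": r.provenance,
        }
        if precision is not None:
            for k in ("phi2_cmax", "phi2_ctrough", "biot"):
                rec[k] = format_value(rec[k], precision)
        recs.append(rec)
    return pd.DataFrame(recs, columns=_COLUMNS)
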