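"""Incremental cost-effectiveness arithmetic.

ICER = delta cost / delta QALYs between two strategies; net monetary benefit
NMB(wtp) = wtp * QALYs - cost. Sign conventions: a strategy that saves money
while gaining QALYs is *dominant* (no ratio is reported), one that costs more
while losing QALYs is *dominated*; with zero QALY difference the ICER is
undefined and only NMB comparisons remain meaningful. The WTP at which the
two strategies' NMB lines cross equals delta C / delta E exactly, which is
the logic behind the acceptability-curve crossing point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .engine import StrategyOutcome

__all__ = ["ICERResult", "CEAResult", "icer", "nmb", "threshold_verdict", "compare"]


@dataclass
class ICERResult:
    delta_cost: float
    delta_qalys: float
    icer: Optional[float]        # None when dominance or zero QALY difference
    label: str                   # "icer" | "dominant" | "dominated" | "undefined"


@dataclass
class CEAResult:
    """Pairwise comparison of an alternative against a reference strategy."""

    reference: str
    alternative: str
    totals: dict[str, dict[str, float]]      # arm -> {cost, qalys}
    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    label: str
    nmb: dict[str, dict[str, float]] = field(default_factory=dict)   # arm -> region -> NMB
    verdicts: dict[str, bool] = field(default_factory=dict)          # region -> cost-effective

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Base-case results table: one column per arm plus increments."""
        rows = []
        for arm, tot in self.totals.items():
            rows.append({"strategy": arm, "total_cost": tot["cost"],
                         "total_qalys": tot["qalys"]})
        frame = pd.DataFrame(rows).set_index("strategy")
        frame.loc["increment"] = [self.delta_cost, self.delta_qalys]
        return frame


def icer(ref: StrategyOutcome, alt: StrategyOutcome) -> ICERResult:
    """Incremental cost-effectiveness ratio of ``alt`` versus ``ref``."""
    dc = alt.total_cost - ref.total_cost
    de = alt.total_qalys - ref.total_qalys
    if de == 0:
        return ICERResult(dc, de, None, "undefined")
    if dc < 0 and de > 0:
        return ICERResult(dc, de, None, "dominant")
    if dc > 0 and de < 0:
        return ICERResult(dc, de, None, "dominated")
    return ICERResult(dc, de, dc / de, "icer")


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (USD)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.total_qalys - outcome.total_cost


def threshold_verdict(
    icer_value: float, thresholds: dict[str, float]
) -> dict[str, bool]:
    """Cost-effective flag per region; the boundary ICER == WTP counts as
    cost-effective (inclusive convention)."""
    for region, wtp in thresholds.items():
        if wtp <= 0:
            raise ValueError(f"threshold for region '{region}' must be positive")
    return {region: icer_value <= wtp for region, wtp in thresholds.items()}


def compare(
    ref: StrategyOutcome,
    alt: StrategyOutcome,
    wtp_thresholds: Optional[dict[str, float]] = None,
) -> CEAResult:
    """Full pairwise comparison: totals, increments, ICER, NMB, verdicts."""
    inc = icer(ref, alt)
    result = CEAResult(
        reference=ref.arm,
        alternative=alt.arm,
        totals={
            ref.arm: {"cost": ref.total_cost, "qalys": ref.total_qalys},
            alt.arm: {"cost": alt.total_cost, "qalys": alt.total_qalys},
        },
        delta_cost=inc.delta_cost,
        delta_qalys=inc.delta_qalys,
        icer=inc.icer,
        label=inc.label,
    )
    if wtp_thresholds:
        for arm, out in ((ref.arm, ref), (alt.arm, alt)):
            result.nmb[arm] = {r: nmb(out, w) for r, w in wtp_thresholds.items()}
        if inc.label == "dominant":
            result.verdicts = {r: True for r in wtp_thresholds}
        elif inc.label == "dominated":
            result.verdicts = {r: False for r in wtp_thresholds}
        elif inc.icer is not None:
            result.verdicts = threshold_verdict(inc.icer, wtp_thresholds)
    return result
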