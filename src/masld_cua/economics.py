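"""Deterministic cost-utility arithmetic.

Program costing from itemized monthly components, HICP inflation
adjustment, the incremental cost-effectiveness ratio

    ICER = (C1 - C0) / (E1 - E0)

against a no-program comparator (C0 = 0, E0 = 0 by default), and the net
monetary benefit NMB = QALY_gain * WTP - Cost at configurable
willingness-to-pay thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

#: Default willingness-to-pay thresholds (EUR per QALY) commonly applied
#: in Italian / European health-technology assessment.
DEFAULT_WTP = (25_000.0, 30_000.0, 40_000.0)


@dataclass(frozen=True)
class CostModel:
    """Itemized direct monthly program costs per patient.

    Defaults are the supervised-exercise program's components: gym
    membership EUR 30, expert supervision EUR 60, project management
    EUR 20, insurance EUR 10 per month, over a 12-month program.
    """

    components: tuple[tuple[str, float], ...] = (
        ("gym membership", 30.0),
        ("expert supervision", 60.0),
        ("project management", 20.0),
        ("insurance policy", 10.0),
    )
    months: int = 12

    def __post_init__(self) -> None:
        for label, monthly in self.components:
            if monthly < 0:
                raise ValueError(f"negative monthly cost for {label!r}: {monthly}")
        if self.months < 0:
            raise ValueError(f"months must be non-negative, got {self.months}")

    @property
    def monthly_total(self) -> float:
        return sum(monthly for _, monthly in self.components)


def total_program_cost(model: CostModel) -> float:
    """Annual (or ``model.months``-month) program cost per patient in EUR."""
    return model.monthly_total * model.months


def adjust_hicp(cost: float, index_from: float, index_to: float) -> float:
    """Re-express a cost in another year's euros via HICP index values.

    The harmonized index of consumer prices values (e.g. Eurostat Euro
    area, base 2015 = 100) are parameters: the function never fetches
    them.
    """
    if index_from <= 0 or index_to <= 0:
        raise ValueError(
            f"HICP indices must be positive, got from={index_from}, to={index_to}"
        )
    return cost * index_to / index_from


@dataclass(frozen=True)
class EconomicInputs:
    """Incremental cost and effect inputs of the cost-utility comparison.

    ``c1``/``e1`` are the program arm's mean per-patient cost (EUR) and
    effect (QALYs); ``c0``/``e0`` the comparator's, fixed at zero for the
    no-program scenario.
    """

    c1: float
    e1: float
    c0: float = 0.0
    e0: float = 0.0

    @property
    def delta_cost(self) -> float:
        return self.c1 - self.c0

    @property
    def delta_effect(self) -> float:
        return self.e1 - self.e0


@dataclass(frozen=True)
class ThresholdSet:
    """Willingness-to-pay thresholds in EUR per QALY."""

    wtp: tuple[float, ...] = DEFAULT_WTP

    def __post_init__(self) -> None:
        if not self.wtp:
            raise ValueError("at least one WTP threshold is required")
        if any(w < 0 for w in self.wtp):
            raise ValueError(f"WTP thresholds must be non-negative: {self.wtp}")


@dataclass(frozen=True)
class Icer:
    """ICER outcome: a EUR/QALY ratio or a dominance label.

    ``label`` is ``"ratio"`` when ``value`` is a meaningful EUR/QALY
    figure, ``"dominant"`` when the program saves money and gains QALYs,
    ``"dominated"`` when it costs more and loses QALYs, and
    ``"undefined"`` when the effect difference is exactly zero (``value``
    is NaN in the non-ratio cases).
    """

    value: float
    label: str

    @property
    def is_ratio(self) -> bool:
        return self.label == "ratio"


def compute_icer(inputs: EconomicInputs) -> Icer:
    """ICER with explicit dominance handling; never raises on ΔE = 0."""
    dc, de = inputs.delta_cost, inputs.delta_effect
    if de == 0:
        return Icer(value=math.nan, label="undefined")
    if dc < 0 and de > 0:
        return Icer(value=math.nan, label="dominant")
    if dc > 0 and de < 0:
        return Icer(value=math.nan, label="dominated")
    return Icer(value=dc / de, label="ratio")


def compute_nmb(qaly_gain: float, wtp: float, cost: float) -> float:
    """Net monetary benefit: ``qaly_gain * wtp - cost`` in EUR."""
    if wtp < 0:
        raise ValueError(f"WTP must be non-negative, got {wtp}")
    return qaly_gain * wtp - cost


def nmb_table(inputs: EconomicInputs, thresholds: ThresholdSet) -> dict[float, float]:
    """NMB at each threshold for the incremental cost/effect pair."""
    return {
        w: compute_nmb(inputs.delta_effect, w, inputs.delta_cost)
        for w in thresholds.wtp
    }
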