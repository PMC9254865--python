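"""Attach costs and utilities to a partitioned-survival trace.

Cost components follow the usual Chinese-health-system costing surface for
first-line oncology regimens: drug acquisition while progression-free,
subsequent therapy or best supportive care while progressed, per-cycle
follow-up and hospital management while alive, a one-off grade>=3
adverse-event burden at model entry, and terminal care on death. All flows
are discounted with the trace's per-cycle weights; amounts are plain RMB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .engine import DAYS_PER_YEAR, Trace

import numpy as np

__all__ = [
    "DrugComponent",
    "InfusionComponent",
    "AdverseEvent",
    "StrategyInputs",
    "CostBreakdown",
    "OutcomeAccumulation",
    "cycle_drug_cost",
    "one_off_event_burden",
    "accumulate_strategy",
]


@dataclass(frozen=True)
class DrugComponent:
    """An oral drug: unit price x units per day, on a fraction of days.

    ``dosed_fraction`` handles intermittent schedules such as sunitinib's
    4-weeks-on / 2-weeks-off pattern (steady-state fraction 28/42).
    """

    name: str
    unit_price: float
    units_per_day: float
    dosed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_price < 0:
            raise ValueError(f"negative price for {self.name}")
        if self.units_per_day < 0:
            raise ValueError(f"negative units_per_day for {self.name}")
        if not (0.0 < self.dosed_fraction <= 1.0):
            raise ValueError(f"dosed_fraction must be in (0, 1] for {self.name}")

    @property
    def daily_cost(self) -> float:
        return self.unit_price * self.units_per_day


@dataclass(frozen=True)
class InfusionComponent:
    """An infused drug billed per cycle (e.g. pembrolizumab mg x per-mg price)."""

    name: str
    price_per_unit: float
    units_per_cycle: float

    def __post_init__(self) -> None:
        if self.price_per_unit < 0:
            raise ValueError(f"negative price for {self.name}")
        if self.units_per_cycle < 0:
            raise ValueError(f"negative units_per_cycle for {self.name}")

    @property
    def cost_per_cycle(self) -> float:
        return self.price_per_unit * self.units_per_cycle


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float  # grade >= 3 incidence over the treatment course
    unit_cost: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError(f"incidence outside [0,1] for {self.name}")
        if self.unit_cost < 0:
            raise ValueError(f"negative cost for {self.name}")


@dataclass
class StrategyInputs:
    """Everything needed to value one treatment strategy on a trace."""

    name: str
    oral: list[DrugComponent] = field(default_factory=list)
    infusion: list[InfusionComponent] = field(default_factory=list)
    subsequent_cost_per_cycle: float = 0.0
    subsequent_proportion: float = 0.0
    ae_profile: list[AdverseEvent] = field(default_factory=list)
    discontinuation_prob_ae: float = 0.0
    apply_discontinuation: bool = False  # optional mode, off in the base case
    discontinuation_ramp_cycles: int = 17  # ~1 year of 21-day cycles
    u_pfs: float = 1.0
    u_pd: float = 1.0
    ae_disutility: float = 0.0
    ae_duration_years: float = 28.0 / DAYS_PER_YEAR  # default 4 weeks
    followup_cost_per_cycle: float = 0.0
    management_cost_per_cycle: float = 0.0
    bsc_cost_per_cycle: float = 0.0
    terminal_care_cost: float = 0.0

    def __post_init__(self) -> None:
        for attr in (
            "subsequent_cost_per_cycle",
            "followup_cost_per_cycle",
            "management_cost_per_cycle",
            "bsc_cost_per_cycle",
            "terminal_care_cost",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")
        for attr in ("subsequent_proportion", "u_pfs", "u_pd", "discontinuation_prob_ae"):
            if not (0.0 <= getattr(self, attr) <= 1.0):
                raise ValueError(f"{self.name}: {attr} must be in [0, 1]")
        if self.ae_disutility < 0:
            raise ValueError(f"{self.name}: ae_disutility must be >= 0")
        if self.u_pfs < self.u_pd:
            warnings.warn(f"{self.name}: u_pfs < u_pd is unusual", stacklevel=2)


@dataclass
class CostBreakdown:
    """Discounted cost components (RMB); total is their sum."""

    first_line: float = 0.0
    subsequent: float = 0.0
    bsc: float = 0.0
    ae: float = 0.0
    followup: float = 0.0
    management: float = 0.0
    terminal: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.first_line
            + self.subsequent
            + self.bsc
            + self.ae
            + self.followup
            + self.management
            + self.terminal
        )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in (
            "first_line", "subsequent", "bsc", "ae", "followup", "management", "terminal")}
        d["total"] = self.total
        return d


@dataclass
class OutcomeAccumulation:
    """Discounted life-years and QALYs (plus undiscounted LY)."""

    ly: float
    qaly: float
    ly_undiscounted: float


def cycle_drug_cost(inputs: StrategyInputs, cycle_index: int = 0,
                    cycle_length_days: float = 21.0) -> float:
    """First-line acquisition cost for one cycle (infusion + oral components).

    Applied to the progression-free state only (the weighting by occupancy
    happens in :func:`accumulate_strategy`). The optional AE-discontinuation
    mode phases out ``discontinuation_prob_ae`` of drug cost linearly over
    the configured ramp; it is off by default.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    oral = sum(c.daily_cost * c.dosed_fraction for c in inputs.oral) * cycle_length_days
    infusion = sum(c.cost_per_cycle for c in inputs.infusion)
    cost = oral + infusion
    if inputs.apply_discontinuation and inputs.discontinuation_prob_ae > 0:
        phase = min(1.0, cycle_index / max(inputs.discontinuation_ramp_cycles, 1))
        cost *= 1.0 - inputs.discontinuation_prob_ae * phase
    return cost


def one_off_event_burden(inputs: StrategyInputs) -> tuple[float, float]:
    """One-off adverse-event cost and QALY loss applied at model entry.

    ae_cost = sum(incidence_i x unit_cost_i); the QALY loss multiplies the
    grade>=3 disutility by total incidence (capped at 1) and the configured
    event duration.
    """
    ae_cost = sum(a.incidence * a.unit_cost for a in inputs.ae_profile)
    total_inc = min(sum(a.incidence for a in inputs.ae_profile), 1.0)
    ae_qaly_loss = inputs.ae_disutility * total_inc * inputs.ae_duration_years
    return ae_cost, ae_qaly_loss


def accumulate_strategy(
    trace: Trace, inputs: StrategyInputs
) -> tuple[CostBreakdown, OutcomeAccumulation]:
    """Run one strategy's costs and outcomes over a trace.

    Per cycle (all discounted at the midpoint): first-line drugs weight the
    progression-free occupancy; progressed patients split between subsequent
    therapy (by the trial's subsequent-treatment proportion) and best
    supportive care; follow-up and management apply to everyone alive;
    terminal care is billed on incident deaths. QALYs weight occupancy by
    the state utilities; the AE burden enters once, undiscounted, at t=0.
    """
    w = trace.discount
    cyc_years = trace.cycle_years
    cycle_days = trace.grid.cycle_length_days

    drug = np.array(
        [cycle_drug_cost(inputs, i, cycle_days) for i in range(trace.n_cycles)]
    )
    alive = trace.occ_pfs + trace.occ_pd

    first_line = float(np.sum(w * drug * trace.occ_pfs))
    subsequent = float(
        np.sum(w * trace.occ_pd) * inputs.subsequent_proportion * inputs.subsequent_cost_per_cycle
    )
    bsc = float(
        np.sum(w * trace.occ_pd) * (1.0 - inputs.subsequent_proportion) * inputs.bsc_cost_per_cycle
    )
    followup = float(np.sum(w * alive) * inputs.followup_cost_per_cycle)
    management = float(np.sum(w * alive) * inputs.management_cost_per_cycle)
    terminal = float(np.sum(w * trace.incident_deaths) * inputs.terminal_care_cost)
    ae_cost, ae_qaly_loss = one_off_event_burden(inputs)

    ly = float(cyc_years * np.sum(w * alive))
    ly_undisc = float(cyc_years * np.sum(alive))
    qaly = float(
        cyc_years * np.sum(w * (inputs.u_pfs * trace.occ_pfs + inputs.u_pd * trace.occ_pd))
    ) - ae_qaly_loss

    costs = CostBreakdown(
        first_line=first_line,
        subsequent=subsequent,
        bsc=bsc,
        ae=ae_cost,
        followup=followup,
        management=management,
        terminal=terminal,
    )
    return costs, OutcomeAccumulation(ly=ly, qaly=qaly, ly_undiscounted=ly_undisc)
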