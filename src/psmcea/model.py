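"""Model/Results objects tying the partitioned-survival pipeline together.

`PartitionedSurvivalModel` is constructed from a validated configuration
(or the shipped fixture calibration); `fit()` evaluates the base case and
returns a `PSMResults` object that carries per-strategy discounted costs,
life-years and QALYs, exposes the incremental table and a printable
summary, and runs the sensitivity, scenario and subgroup analyses.

    >>> model = PartitionedSurvivalModel.clear_fixture()
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import decision
from .config import ModelConfig, load_and_validate
from .curves import (
    SurvivalFunction,
    apply_hazard_ratio,
    fit_all_families,
    select_distribution,
)
from .decision import ParameterSpec, StrategyResult
from .engine import DAYS_PER_YEAR, CycleGrid, Trace, build_trace
from .reconstruct import DigitizedCurve, RiskTable, reconstruct_ipd
from .synthetic import (
    calibrate_exponential_from_discounted_ly,
    calibrate_weibull_from_median,
)
from .valuation import (
    AdverseEvent,
    CostBreakdown,
    DrugComponent,
    InfusionComponent,
    OutcomeAccumulation,
    StrategyInputs,
    accumulate_strategy,
)

__all__ = ["PartitionedSurvivalModel", "PSMResults"]


class ConfigPathError(KeyError):
    """A parameter path does not resolve into the model inputs."""


def _apply_path(tree, path: str, value: float) -> None:
    tokens = path.split(".")
    node = tree
    try:
        for tok in tokens[:-1]:
            node = node[int(tok)] if isinstance(node, list) else node[tok]
        last = tokens[-1]
        if isinstance(node, list):
            node[int(last)] = value
        else:
            if last not in node:
                raise KeyError(last)
            node[last] = value
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise ConfigPathError(f"parameter path {path!r} not found") from exc


class PartitionedSurvivalModel:
    """Three-state partitioned-survival cost-utility model.

    State occupancy is read off per-strategy PFS and OS curves on a 21-day
    cycle grid; costs and utilities attach per cycle with annual
    discounting. Curves are resolved once at construction (calibrations,
    hazard-ratio derivations, or fits to digitized CSV artifacts) and held
    fixed through the sensitivity analyses, which vary only the cost and
    utility parameters.
    """

    def __init__(self, config: ModelConfig, base_dir: Path | str | None = None):
        self.config = config
        self.base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
        self._base_tree = config.model_dump()
        self.reference: str = config.reference
        self.comparators: list[str] = [
            n for n in config.strategies if n != self.reference
        ]
        self.params: dict[str, ParameterSpec] = {
            p.name: ParameterSpec(
                p.name, p.base, p.low, p.high, p.distribution, tuple(p.paths)
            )
            for p in config.parameters
        }
        # fail fast on unresolvable paths
        probe = copy.deepcopy(self._base_tree)
        for p in self.params.values():
            for path in p.paths:
                _apply_path(probe, path, p.base)
        self.curves = self._resolve_curves()
        self._trace_cache: dict[tuple, Trace] = {}

    # -- constructors --------------------------------------------------

    @classmethod
    def from_config(cls, source, base_dir=None) -> "PartitionedSurvivalModel":
        """Build from a ModelConfig, a raw dict, or a YAML/JSON file path."""
        if isinstance(source, ModelConfig):
            return cls(source, base_dir)
        if isinstance(source, (str, Path)):
            return cls(load_and_validate(source), base_dir or Path(source).parent)
        return cls(ModelConfig.model_validate(source), base_dir)

    @classmethod
    def clear_fixture(cls) -> "PartitionedSurvivalModel":
        """The shipped surrogate calibration of the published analysis."""
        from .fixtures import clear_like_config

        return cls(clear_like_config())

    # -- curve resolution ----------------------------------------------

    def _resolve_curves(self) -> dict[str, dict[str, object]]:
        cfg = self.config
        curves: dict[str, dict[str, object]] = {n: {} for n in cfg.strategies}
        pending = [
            (name, ep, c)
            for name, s in cfg.strategies.items()
            for ep, c in s.curves.items()
        ]
        for _ in range(len(pending) + 1):
            later = []
            for name, ep, c in pending:
                if c.source == "hazard_ratio":
                    ref_curves = curves.get(c.reference, {})
                    if ep not in ref_curves:
                        later.append((name, ep, c))
                        continue
                    curves[name][ep] = apply_hazard_ratio(ref_curves[ep], c.hr)
                elif c.source == "parametric":
                    curves[name][ep] = SurvivalFunction(c.family, c.params, "months")
                elif c.source == "weibull_median":
                    curves[name][ep] = calibrate_weibull_from_median(
                        c.median_months, c.shape
                    )
                elif c.source == "exponential_discounted_ly":
                    curves[name][ep] = calibrate_exponential_from_discounted_ly(
                        c.target_discounted_ly,
                        cfg.grid.horizon_years,
                        cfg.discount_rate,
                        CycleGrid(cfg.grid.cycle_length_days, cfg.grid.horizon_years),
                    )
                else:  # fit
                    curve = DigitizedCurve.from_csv(self.base_dir / c.curve_csv)
                    risk = RiskTable.from_csv(self.base_dir / c.risk_csv)
                    ipd = reconstruct_ipd(curve, risk, c.total_events)
                    fits = fit_all_families(ipd)
                    curves[name][ep] = select_distribution(fits, c.criterion).function
            if not later:
                break
            if len(later) == len(pending):
                raise ValueError("circular hazard_ratio curve references")
            pending = later
        return curves

    # -- inputs and evaluation -----------------------------------------

    def parameter(self, name: str) -> ParameterSpec:
        try:
            return self.params[name]
        except KeyError:
            raise ConfigPathError(f"unknown parameter {name!r}") from None

    def _tree_with(
        self,
        overrides: Mapping[str, float] | None,
        path_lookup: Mapping[str, tuple[str, ...]] | None = None,
    ) -> dict:
        tree = copy.deepcopy(self._base_tree)
        for name, value in (overrides or {}).items():
            paths = (path_lookup or {}).get(name) or self.parameter(name).paths
            for path in paths:
                _apply_path(tree, path, value)
        return tree

    def make_runner(self, specs: Sequence[ParameterSpec]):
        """A run() closure that resolves the given specs' names to paths
        (falling back to the registered parameters)."""
        lookup = {s.name: tuple(s.paths) for s in specs}

        def runner(overrides=None, horizon_years=None, curves=None):
            return self.run(overrides, horizon_years, curves, path_lookup=lookup)

        return runner

    def _inputs_from_tree(self, tree: dict) -> dict[str, StrategyInputs]:
        shared = tree["shared"]
        followup = sum(shared["followup_cost_per_cycle"].values())
        management = sum(shared["management_cost_per_cycle"].values())
        inputs = {}
        for name, s in tree["strategies"].items():
            inputs[name] = StrategyInputs(
                name=name,
                oral=[DrugComponent(d["name"], d["unit_price"], d["units_per_day"],
                                    d["dosed_fraction"]) for d in s["oral"]],
                infusion=[InfusionComponent(d["name"], d["price_per_unit"],
                                            d["units_per_cycle"]) for d in s["infusion"]],
                subsequent_cost_per_cycle=s["subsequent_cost_per_cycle"],
                subsequent_proportion=s["subsequent_proportion"],
                ae_profile=[
                    AdverseEvent(a["name"], a["incidence"],
                                 shared["ae_unit_costs"][a["name"]])
                    for a in s["ae_incidence"]
                ],
                discontinuation_prob_ae=s["discontinuation_prob_ae"],
                u_pfs=s["u_pfs"],
                u_pd=s["u_pd"],
                ae_disutility=shared["ae_disutility"],
                ae_duration_years=shared["ae_duration_weeks"] * 7.0 / DAYS_PER_YEAR,
                followup_cost_per_cycle=followup,
                management_cost_per_cycle=management,
                bsc_cost_per_cycle=shared["bsc_cost_per_cycle"],
                terminal_care_cost=shared["terminal_care_cost"],
            )
        return inputs

    def trace_for(
        self,
        strategy: str,
        horizon_years: float | None = None,
        discount_rate: float | None = None,
        curves: Mapping[str, Mapping[str, object]] | None = None,
    ) -> Trace:
        """Occupancy trace for one strategy (cached for the base curves)."""
        cfg = self.config
        horizon = horizon_years if horizon_years is not None else cfg.grid.horizon_years
        rate = discount_rate if discount_rate is not None else cfg.discount_rate
        cacheable = curves is None
        key = (strategy, horizon, rate)
        if cacheable and key in self._trace_cache:
            return self._trace_cache[key]
        cset = (curves or self.curves)[strategy]
        grid = CycleGrid(cfg.grid.cycle_length_days, horizon)
        trace = build_trace(cset["pfs"], cset["os"], grid, rate)
        if cacheable:
            self._trace_cache[key] = trace
        return trace

    def run_detailed(
        self,
        overrides: Mapping[str, float] | None = None,
        horizon_years: float | None = None,
        curves=None,
        path_lookup: Mapping[str, tuple[str, ...]] | None = None,
    ) -> dict[str, tuple[CostBreakdown, OutcomeAccumulation]]:
        """Value every strategy; returns cost breakdowns and outcomes."""
        tree = self._tree_with(overrides, path_lookup)
        inputs = self._inputs_from_tree(tree)
        rate = tree["discount_rate"]
        out = {}
        for name, strat_inputs in inputs.items():
            trace = self.trace_for(name, horizon_years, rate, curves)
            out[name] = accumulate_strategy(trace, strat_inputs)
        return out

    def run(
        self,
        overrides: Mapping[str, float] | None = None,
        horizon_years: float | None = None,
        curves=None,
        path_lookup: Mapping[str, tuple[str, ...]] | None = None,
    ) -> dict[str, StrategyResult]:
        """Value every strategy; returns discounted totals per strategy."""
        detailed = self.run_detailed(overrides, horizon_years, curves, path_lookup)
        return {
            name: StrategyResult(name, cb.total, oa.qaly, oa.ly)
            for name, (cb, oa) in detailed.items()
        }

    def fit(self) -> "PSMResults":
        """Evaluate the base case and wrap it in a results object."""
        detailed = self.run_detailed()
        return PSMResults(self, detailed)


class PSMResults:
    """Base-case results plus the sensitivity/scenario/subgroup runners."""

    def __init__(self, model: PartitionedSurvivalModel, detailed):
        self.model = model
        self.breakdowns = {n: cb for n, (cb, _) in detailed.items()}
        self.outcomes = {n: oa for n, (_, oa) in detailed.items()}
        self.strategy_results = {
            n: StrategyResult(n, cb.total, oa.qaly, oa.ly)
            for n, (cb, oa) in detailed.items()
        }
        self.traces = {n: model.trace_for(n) for n in detailed}

    # -- base case -----------------------------------------------------

    @property
    def reference(self) -> str:
        return self.model.reference

    def icer_table(self) -> list[decision.IncrementalRow]:
        return decision.icer_table(
            list(self.strategy_results.values()), self.reference
        )

    def net_monetary_benefit(self, wtp: float) -> dict[str, float]:
        return {
            n: decision.net_monetary_benefit(r, wtp)
            for n, r in self.strategy_results.items()
        }

    def results_frame(self) -> pd.DataFrame:
        rows = []
        inc = {r.comparator: r for r in self.icer_table()}
        order = [self.reference] + self.model.comparators
        for name in order:
            r = self.strategy_results[name]
            row = {
                "strategy": name,
                "ly": r.ly,
                "qaly": r.qaly,
                "cost": r.cost,
                "incremental_qaly": np.nan,
                "incremental_cost": np.nan,
                "icer": np.nan,
            }
            if name in inc:
                row["incremental_qaly"] = inc[name].delta_qaly
                row["incremental_cost"] = inc[name].delta_cost
                row["icer"] = inc[name].icer if inc[name].icer is not None else np.inf
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Printable base-case table (LY, QALY, increments, cost, ICER)."""
        df = self.results_frame()
        wtp1, wtp3 = self.model.config.wtp_thresholds
        lines = [
            "Partitioned survival cost-utility analysis — base case",
            f"horizon {self.model.config.grid.horizon_years:g} y, "
            f"cycle {self.model.config.grid.cycle_length_days:g} d, "
            f"discount {self.model.config.discount_rate:.1%}, "
            f"reference: {self.reference}",
            "",
            df.to_string(
                index=False,
                float_format=lambda x: f"{x:,.2f}" if abs(x) < 100 else f"{x:,.0f}",
            ),
            "",
            f"willingness-to-pay thresholds: {wtp1:,.0f} (1x GDP) / {wtp3:,.0f} (3x GDP) RMB/QALY",
        ]
        return "\n".join(lines)

    # -- analyses ------------------------------------------------------

    def one_way_dsa(
        self,
        pair: tuple[str, str] | None = None,
        params: Sequence[ParameterSpec] | None = None,
    ) -> list[decision.TornadoEntry]:
        pair = pair or (self.model.comparators[-1], self.reference)
        params = params if params is not None else list(self.model.params.values())
        return decision.one_way_dsa(self.model.make_runner(params), params, pair)

    def tornado_frame(self, pair=None) -> pd.DataFrame:
        entries = self.one_way_dsa(pair)
        return pd.DataFrame(
            [
                {"parameter": e.name, "icer_low": e.icer_low,
                 "icer_high": e.icer_high, "width": e.width}
                for e in entries
            ]
        )

    def run_psa(
        self,
        n_iter: int | None = None,
        seed: int = 0,
        wtp_grid=None,
    ) -> decision.PSAResult:
        cfg = self.model.config.psa
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, cfg.wtp_max + cfg.wtp_step / 2, cfg.wtp_step)
        sampled = [
            p for p in self.model.params.values() if p.distribution != "fixed"
        ]
        return decision.run_psa_and_ceac(
            self.model.run,
            sampled,
            self.reference,
            n_iter=n_iter or cfg.n_iter,
            wtp_grid=wtp_grid,
            seed=seed,
        )

    def scenarios(self, pair: tuple[str, str] | None = None) -> dict:
        s = self.model.config.scenarios
        return decision.run_scenarios(
            self.model,
            horizons_years=s.horizons_years,
            price_parameter=s.price_parameter,
            price_reductions=s.price_reductions,
            pair=pair,
        )

    def subgroup(self, label: str, hr_pfs: float, hr_os: float,
                 comparator: str | None = None) -> dict:
        return decision.run_subgroup(self.model, label, hr_pfs, hr_os, comparator)

    def subgroups(self) -> list[dict]:
        return [
            self.subgroup(s.label, s.hr_pfs, s.hr_os, s.comparator)
            for s in self.model.config.subgroups
        ]
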