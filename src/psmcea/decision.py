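"""Incremental cost-effectiveness analysis and sensitivity analyses.

Covers the decision layer of the cost-utility study: pairwise incremental
cost-effectiveness ratios with dominance labelling, net monetary benefit,
one-way (tornado) deterministic sensitivity analysis, probabilistic
sensitivity analysis with cost-effectiveness acceptability curves, and the
horizon / drug-price scenario and hazard-ratio subgroup runners.

The probabilistic analysis follows the usual convention for range-only
published inputs: each parameter's printed range is read as a central 95%
interval (sd = range / 3.92), and gamma (costs) or beta (bounded
quantities) distributions are moment-matched to that mean and sd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrategyResult",
    "IncrementalRow",
    "ParameterSpec",
    "TornadoEntry",
    "PSAResult",
    "icer_table",
    "net_monetary_benefit",
    "one_way_dsa",
    "sample_psa_parameters",
    "run_psa_and_ceac",
    "run_scenarios",
    "run_subgroup",
]

RANGE_TO_SD = 3.92  # range read as a 95% interval: sd = (high - low) / 3.92


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals for one strategy."""

    name: str
    cost: float
    qaly: float
    ly: float


@dataclass(frozen=True)
class IncrementalRow:
    """Pairwise increment of a comparator over the reference strategy."""

    comparator: str
    reference: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str = ""  # "", "dominant", or "dominated"


@dataclass(frozen=True)
class ParameterSpec:
    """A model input with its base value, range, and PSA distribution.

    ``paths`` are dot-paths into the resolved model-input tree (integer
    tokens index lists); one parameter may drive several paths, e.g. a drug
    price shared by two strategies. ``distribution`` "fixed" means the
    parameter is varied in the one-way analysis but never sampled in PSA.
    """

    name: str
    base: float
    low: float
    high: float
    distribution: str  # "gamma" | "beta" | "fixed"
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not (0.0 < self.base < 1.0):
            raise ValueError(f"{self.name}: beta requires mean in (0, 1)")
        if self.distribution == "gamma" and self.base < 0:
            raise ValueError(f"{self.name}: gamma requires nonnegative mean")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / RANGE_TO_SD

    def moment_matched(self) -> dict[str, float]:
        """Distribution constants implied by (base, range)."""
        sd = self.sd
        if self.distribution == "gamma":
            shape = self.base**2 / sd**2
            return {"shape": shape, "scale": sd**2 / self.base}
        if self.distribution == "beta":
            nu = self.base * (1.0 - self.base) / sd**2 - 1.0
            if nu <= 0:
                raise ValueError(f"{self.name}: range too wide for a beta distribution")
            return {"alpha": self.base * nu, "beta": (1.0 - self.base) * nu}
        return {}


def icer_table(
    results: Sequence[StrategyResult], reference: str
) -> list[IncrementalRow]:
    """Pairwise increments of every strategy versus the reference.

    ICER = delta cost / delta QALY when both have the same decision-relevant
    sign; a cheaper-and-better comparator is "dominant", a dearer-and-worse
    one "dominated".
    """
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among strategies")
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    ref = next(r for r in results if r.name == reference)
    rows = []
    for r in results:
        if r.name == reference:
            continue
        dc, dq = r.cost - ref.cost, r.qaly - ref.qaly
        label = ""
        icer: float | None
        if dq == 0:
            icer = None
        else:
            icer = dc / dq
            if dc <= 0 and dq > 0:
                label = "dominant"
            elif dc > 0 and dq < 0:
                label = "dominated"
        rows.append(IncrementalRow(r.name, reference, dc, dq, icer, label))
    return rows


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """wtp x QALY - cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * result.qaly - result.cost


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


Runner = Callable[..., dict[str, StrategyResult]]


def _pair_icer(results: Mapping[str, StrategyResult], pair: tuple[str, str]) -> float:
    comp, ref = pair
    row = icer_table([results[comp], results[ref]], ref)[0]
    if row.icer is None:
        return math.inf
    return row.icer


def one_way_dsa(
    runner: Runner,
    params: Sequence[ParameterSpec],
    pair: tuple[str, str],
) -> list[TornadoEntry]:
    """Tornado analysis: each parameter to its low then high bound, others
    at base; entries sorted by ICER-interval width, widest first."""
    entries = []
    with warnings.catch_warnings():
        # bound sweeps can transiently invert u_pfs >= u_pd; expected here
        warnings.simplefilter("ignore", UserWarning)
        for p in params:
            icer_lo = _pair_icer(runner(overrides={p.name: p.low}), pair)
            icer_hi = _pair_icer(runner(overrides={p.name: p.high}), pair)
            entries.append(TornadoEntry(p.name, icer_lo, icer_hi))
    return sorted(entries, key=lambda e: -e.width)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def sample_psa_parameters(
    params: Sequence[ParameterSpec], n_iter: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Moment-matched parameter draws, one column per sampled parameter.

    Costs draw from gamma, bounded quantities from beta; "fixed" parameters
    are excluded. Deterministic given the seed (parameters sampled in list
    order from one generator stream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for p in params:
        if p.distribution == "fixed":
            continue
        if p.sd == 0:
            cols[p.name] = np.full(n_iter, p.base)
            continue
        m = p.moment_matched()
        if p.distribution == "gamma":
            cols[p.name] = rng.gamma(m["shape"], m["scale"], size=n_iter)
        else:
            cols[p.name] = rng.beta(m["alpha"], m["beta"], size=n_iter)
    return pd.DataFrame(cols)


@dataclass
class PSAResult:
    """Samples, acceptability curves, and incremental-plane summaries."""

    samples: pd.DataFrame  # columns: iteration, strategy, cost, qaly
    ceac: pd.DataFrame  # columns: wtp, one probability column per strategy
    quadrants: dict[str, dict[str, float]]  # per comparator vs reference
    reference: str
    n_failures: int = 0

    def ceac_pairwise(self, comparator: str, wtp_grid=None) -> pd.DataFrame:
        """P(comparator NMB > reference NMB) across willingness-to-pay."""
        wide_c = self._wide(comparator)
        wide_r = self._wide(self.reference)
        grid = np.asarray(
            wtp_grid if wtp_grid is not None else self.ceac["wtp"].to_numpy(), dtype=float
        )
        dq = wide_c["qaly"].to_numpy() - wide_r["qaly"].to_numpy()
        dc = wide_c["cost"].to_numpy() - wide_r["cost"].to_numpy()
        prob = [(w * dq - dc > 0).mean() for w in grid]
        return pd.DataFrame({"wtp": grid, "probability": prob})

    def _wide(self, strategy: str) -> pd.DataFrame:
        df = self.samples[self.samples["strategy"] == strategy]
        return df.sort_values("iteration").reset_index(drop=True)


def run_psa_and_ceac(
    runner: Runner,
    params: Sequence[ParameterSpec],
    reference: str,
    n_iter: int = 10_000,
    wtp_grid=None,
    seed: int = 0,
    max_failure_fraction: float = 0.01,
) -> PSAResult:
    """Monte-Carlo PSA over the parameter distributions on fixed curves.

    Each iteration samples all non-fixed parameters, re-values every
    strategy, and records (cost, QALY). The CEAC gives, at each
    willingness-to-pay, the fraction of iterations in which a strategy has
    the highest net monetary benefit; the probabilities partition to 1.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 1_000_001.0, 10_000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    draws = sample_psa_parameters(params, n_iter, seed)

    records = []
    failures = 0
    strategy_names: list[str] | None = None
    columns = {k: draws[k].to_numpy() for k in draws.columns}
    with warnings.catch_warnings():
        # independent utility draws can invert u_pfs >= u_pd; expected here
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n_iter):
            overrides = {k: float(v[i]) for k, v in columns.items()}
            try:
                results = runner(overrides=overrides)
            except Exception:
                failures += 1
                if failures > max_failure_fraction * n_iter:
                    raise RuntimeError(
                        f"more than {max_failure_fraction:.0%} of PSA iterations failed"
                    )
                continue
            if strategy_names is None:
                strategy_names = list(results)
            for name, res in results.items():
                records.append((i, name, res.cost, res.qaly))

    samples = pd.DataFrame(records, columns=["iteration", "strategy", "cost", "qaly"])
    assert strategy_names is not None
    cost = {s: samples.loc[samples.strategy == s, "cost"].to_numpy() for s in strategy_names}
    qaly = {s: samples.loc[samples.strategy == s, "qaly"].to_numpy() for s in strategy_names}

    ceac_cols: dict[str, list[float]] = {s: [] for s in strategy_names}
    for w in wtp_grid:
        nmb = np.column_stack([w * qaly[s] - cost[s] for s in strategy_names])
        best = np.argmax(nmb, axis=1)
        for j, s in enumerate(strategy_names):
            ceac_cols[s].append(float((best == j).mean()))
    ceac = pd.DataFrame({"wtp": wtp_grid, **ceac_cols})

    quadrants: dict[str, dict[str, float]] = {}
    for s in strategy_names:
        if s == reference:
            continue
        dq = qaly[s] - qaly[reference]
        dc = cost[s] - cost[reference]
        quadrants[s] = {
            "ne_more_costly_more_effective": float(((dc > 0) & (dq > 0)).mean()),
            "nw_more_costly_less_effective": float(((dc > 0) & (dq <= 0)).mean()),
            "se_less_costly_more_effective": float(((dc <= 0) & (dq > 0)).mean()),
            "sw_less_costly_less_effective": float(((dc <= 0) & (dq <= 0)).mean()),
        }
    return PSAResult(samples, ceac, quadrants, reference, failures)


# ---------------------------------------------------------------------------
# scenario and subgroup runners
# ---------------------------------------------------------------------------


def run_scenarios(
    model,
    horizons_years: Sequence[float] = (5.0, 10.0, 20.0),
    price_parameter: str = "price_pembrolizumab_per_mg",
    price_reductions: Sequence[float] = (0.0, 0.25, 0.5, 0.75),
    pair: tuple[str, str] | None = None,
) -> dict:
    """Horizon and drug-price scenarios on a fitted model.

    Horizon runs re-extrapolate to each horizon and report, per strategy,
    the fraction of total discounted cost accrued within the first five
    years. Price runs scale only the first-line pembrolizumab acquisition
    price and report the resulting ICER for the comparator pair.
    """
    if any(h <= 0 for h in horizons_years):
        raise ValueError("horizons must be positive")
    pair = pair or (model.comparators[-1], model.reference)

    horizon_report = {}
    for h in horizons_years:
        results = model.run(horizon_years=h)
        by5 = model.run(horizon_years=min(5.0, h))
        entry = {}
        for name, res in results.items():
            frac = by5[name].cost / res.cost if res.cost > 0 else float("nan")
            entry[name] = {
                "cost": res.cost,
                "qaly": res.qaly,
                "ly": res.ly,
                "cost_fraction_first_5y": frac,
            }
        rows = icer_table(list(results.values()), model.reference)
        entry["icer_vs_reference"] = {
            r.comparator: (r.icer if r.icer is not None else float("nan")) for r in rows
        }
        horizon_report[f"{h:g}y"] = entry

    spec = model.parameter(price_parameter)
    base_icer = _pair_icer(model.run(), pair)
    price_report = []
    for red in price_reductions:
        results = model.run(overrides={price_parameter: spec.base * (1.0 - red)})
        icer = _pair_icer(results, pair)
        price_report.append(
            {
                "reduction": red,
                "price": spec.base * (1.0 - red),
                "icer": icer,
                "icer_delta_vs_base": base_icer - icer,
            }
        )
    return {"horizon": horizon_report, "pembrolizumab_price": price_report}


def run_subgroup(
    model,
    label: str,
    hr_pfs: float,
    hr_os: float,
    comparator: str | None = None,
) -> dict:
    """Subgroup analysis via hazard ratios on the reference curves.

    All arms are assumed to share the reference arm's baseline curves; the
    subgroup-specific hazard ratios generate the comparator's curves, and
    the full valuation is re-run.
    """
    if hr_pfs <= 0 or hr_os <= 0:
        raise ValueError("hazard ratios must be > 0")
    from .curves import apply_hazard_ratio

    comparator = comparator or model.comparators[-1]
    base_curves = model.curves
    ref_curves = base_curves[model.reference]
    curves = dict(base_curves)
    curves[comparator] = {
        "pfs": apply_hazard_ratio(ref_curves["pfs"], hr_pfs),
        "os": apply_hazard_ratio(ref_curves["os"], hr_os),
    }
    results = model.run(curves=curves)
    rows = icer_table(list(results.values()), model.reference)
    row = next(r for r in rows if r.comparator == comparator)
    return {
        "label": label,
        "hr_pfs": hr_pfs,
        "hr_os": hr_os,
        "results": {
            name: {"cost": r.cost, "qaly": r.qaly, "ly": r.ly} for name, r in results.items()
        },
        "incremental": {
            "comparator": comparator,
            "delta_cost": row.delta_cost,
            "delta_qaly": row.delta_qaly,
            "icer": row.icer if row.icer is not None else float("nan"),
            "label": row.label,
        },
    }
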