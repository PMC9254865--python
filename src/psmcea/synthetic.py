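"""Synthetic three-arm trial data emulating published RCC survival evidence.

No patient-level data accompany the published curves, so this module
generates trial-like individual patient data calibrated to the printed
summary statistics — progression-free survival medians of 23.9 / 14.7 / 9.2
months and hazard ratios of 0.39 / 0.65 (PFS) and 0.66 / 1.15 (OS) for the
two lenvatinib combinations versus sunitinib — and emits the digitized-curve
and number-at-risk artifacts the reconstruction stage consumes.

The reference overall-survival curve has no printed median (not reached in
the trial), so it is anchored instead: an exponential rate is solved so that
the engine's discounted reference-arm life-years over the model horizon
match the published 2.83.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .curves import SurvivalFunction, apply_hazard_ratio
from .engine import CycleGrid, build_trace
from .reconstruct import DigitizedCurve, PseudoIPD, RiskTable, km_estimate

__all__ = [
    "TrialSummary",
    "SimulatedIPD",
    "CLEAR_LIKE_SUMMARY",
    "calibrate_weibull_from_median",
    "calibrate_exponential_from_discounted_ly",
    "simulate_arm_ipd",
    "emit_km_artifacts",
    "generate_trial_artifacts",
]


@dataclass(frozen=True)
class TrialSummary:
    """Published summary statistics a synthetic trial must honour."""

    arm_names: tuple[str, ...]
    reference: str
    n_per_arm: int
    pfs_median_months: dict[str, float]
    pfs_hr_vs_ref: dict[str, float]
    os_hr_vs_ref: dict[str, float]
    #: anchor for the reference OS curve (no printed median): the engine's
    #: discounted reference life-years over the horizon must equal this
    os_anchor: dict[str, float]
    accrual_months: float = 12.0
    max_followup_months: float = 36.0
    pfs_weibull_shape: float = 1.2

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.reference not in self.arm_names:
            raise ValueError("reference arm missing from arm_names")
        for d in (self.pfs_median_months,):
            if any(v <= 0 for v in d.values()):
                raise ValueError("medians must be > 0")
        for d in (self.pfs_hr_vs_ref, self.os_hr_vs_ref):
            if any(v <= 0 for v in d.values()):
                raise ValueError("hazard ratios must be > 0")
            if abs(d[self.reference] - 1.0) > 1e-12:
                raise ValueError("reference arm hazard ratio must equal 1")
        if self.accrual_months < 0 or self.max_followup_months < self.accrual_months:
            raise ValueError("need max_followup_months >= accrual_months >= 0")


#: default study conditions: three arms of the published trial's scale
CLEAR_LIKE_SUMMARY = TrialSummary(
    arm_names=("sunitinib", "lenvatinib_everolimus", "lenvatinib_pembrolizumab"),
    reference="sunitinib",
    n_per_arm=355,
    pfs_median_months={
        "sunitinib": 9.2,
        "lenvatinib_everolimus": 14.7,
        "lenvatinib_pembrolizumab": 23.9,
    },
    pfs_hr_vs_ref={
        "sunitinib": 1.0,
        "lenvatinib_everolimus": 0.65,
        "lenvatinib_pembrolizumab": 0.39,
    },
    os_hr_vs_ref={
        "sunitinib": 1.0,
        "lenvatinib_everolimus": 1.15,
        "lenvatinib_pembrolizumab": 0.66,
    },
    os_anchor={"discounted_ly": 2.83, "horizon_years": 5.0, "discount_rate": 0.05},
)


@dataclass
class SimulatedIPD:
    """Simulated per-patient records for one arm and endpoint."""

    time: np.ndarray
    event: np.ndarray
    arm: str = ""
    endpoint: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)

    @property
    def n(self) -> int:
        return int(self.time.size)

    def to_pseudo(self) -> PseudoIPD:
        return PseudoIPD(self.time, self.event, provenance=f"{self.arm}/{self.endpoint}")


def calibrate_weibull_from_median(median_months: float, shape: float) -> SurvivalFunction:
    """Weibull spec with S(median) = 0.5 exactly: scale = median / ln(2)^(1/shape)."""
    if median_months <= 0 or shape <= 0:
        raise ValueError("median_months and shape must be > 0")
    scale = median_months / math.log(2.0) ** (1.0 / shape)
    return SurvivalFunction("weibull", {"shape": shape, "scale": scale}, "months")


def calibrate_exponential_from_discounted_ly(
    target_ly: float,
    horizon_years: float = 5.0,
    discount_rate: float = 0.05,
    grid: CycleGrid | None = None,
) -> SurvivalFunction:
    """Exponential OS curve whose engine discounted life-years hit a target.

    Solves the monthly rate by bisection against the actual cycle grid so
    the anchor is exact under the same discretization the model uses.
    """
    if target_ly <= 0:
        raise ValueError("target_ly must be > 0")
    grid = grid or CycleGrid(horizon_years=horizon_years)

    def ly_gap(rate_month: float) -> float:
        fn = SurvivalFunction("exponential", {"rate": rate_month}, "months")
        tr = build_trace(fn, fn, grid, discount_rate)
        return tr.life_years(discounted=True) - target_ly

    rate = optimize.brentq(ly_gap, 1e-8, 5.0, xtol=1e-12)
    return SurvivalFunction("exponential", {"rate": rate}, "months")


def simulate_arm_ipd(
    spec_pfs,
    spec_os,
    n: int,
    accrual_months: float,
    max_followup_months: float,
    seed: int,
) -> tuple[SimulatedIPD, SimulatedIPD]:
    """Draw joint PFS/OS records with administrative censoring.

    Event times come from inverse-transform sampling with one common
    uniform draw per patient for both endpoints, then clipping the latent
    progression time to the death time. The common draw keeps each marginal
    exact whenever the PFS curve lies below the OS curve (the clip is then a
    no-op) while guaranteeing PFS <= OS record-wise — the consistency the
    partitioned-survival structure assumes. Administrative censoring applies
    at max follow-up minus a uniform accrual offset. Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if accrual_months < 0 or max_followup_months < accrual_months:
        raise ValueError("need max_followup_months >= accrual_months >= 0")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.uniform(size=n)  # in (0, 1]: a valid survival probability
    u_accr = rng.uniform(size=n)
    t_os = np.asarray(spec_os.inverse_survival(u), dtype=float)
    t_pfs = np.minimum(np.asarray(spec_pfs.inverse_survival(u), dtype=float), t_os)
    censor = np.maximum(max_followup_months - u_accr * accrual_months, 1e-9)

    def censored(t):
        ev = (t <= censor).astype(int)
        return np.maximum(np.minimum(t, censor), 1e-9), ev

    obs_os, ev_os = censored(t_os)
    obs_pfs, ev_pfs = censored(t_pfs)
    return (
        SimulatedIPD(obs_pfs, ev_pfs, endpoint="PFS", seed=seed),
        SimulatedIPD(obs_os, ev_os, endpoint="OS", seed=seed),
    )


def emit_km_artifacts(
    ipd: SimulatedIPD | PseudoIPD, risk_grid_months
) -> tuple[DigitizedCurve, RiskTable]:
    """Product-limit curve at every step time plus at-risk counts on a grid."""
    grid = np.asarray(risk_grid_months, dtype=float)
    if grid.size == 0 or grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("risk grid must be strictly increasing and start at 0")
    if getattr(ipd, "n", 0) == 0:
        raise ValueError("empty IPD")
    pseudo = ipd.to_pseudo() if isinstance(ipd, SimulatedIPD) else ipd
    curve = km_estimate(pseudo)
    n_risk = np.array([(pseudo.time >= g).sum() for g in grid], dtype=int)
    return curve, RiskTable(grid, n_risk)


def generate_trial_artifacts(
    summary: TrialSummary = CLEAR_LIKE_SUMMARY,
    seed: int = 0,
    risk_grid_step_months: float = 3.0,
    out_dir=None,
) -> dict[str, dict[str, dict[str, object]]]:
    """Simulate every arm and endpoint and emit curve/risk-table artifacts.

    PFS truth curves are Weibull (default shape 1.2) calibrated to each
    arm's printed median; OS truth is the anchored reference exponential
    with the printed hazard ratios applied to the comparator arms. Returns
    ``{arm: {endpoint: {"ipd", "curve", "risk"}}}`` and optionally writes
    the CSV artifacts to ``out_dir``.
    """
    anchor = summary.os_anchor
    os_ref = calibrate_exponential_from_discounted_ly(
        anchor["discounted_ly"],
        anchor.get("horizon_years", 5.0),
        anchor.get("discount_rate", 0.05),
    )
    ss = np.random.SeedSequence(seed)
    arm_seeds = {
        arm: int(child.generate_state(1)[0] % (2**31))
        for arm, child in zip(summary.arm_names, ss.spawn(len(summary.arm_names)))
    }
    horizon_m = summary.max_followup_months
    grid = np.arange(0.0, horizon_m + risk_grid_step_months / 2, risk_grid_step_months)

    out: dict[str, dict[str, dict[str, object]]] = {}
    for arm in summary.arm_names:
        spec_pfs = calibrate_weibull_from_median(
            summary.pfs_median_months[arm], summary.pfs_weibull_shape
        )
        hr_os = summary.os_hr_vs_ref[arm]
        spec_os = os_ref if arm == summary.reference else apply_hazard_ratio(os_ref, hr_os)
        ipd_pfs, ipd_os = simulate_arm_ipd(
            spec_pfs,
            spec_os,
            summary.n_per_arm,
            summary.accrual_months,
            summary.max_followup_months,
            arm_seeds[arm],
        )
        out[arm] = {}
        for ipd in (ipd_pfs, ipd_os):
            ipd.arm = arm
            curve, risk = emit_km_artifacts(ipd, grid)
            curve.arm, curve.endpoint = arm, ipd.endpoint
            out[arm][ipd.endpoint] = {"ipd": ipd, "curve": curve, "risk": risk}
            if out_dir is not None:
                from pathlib import Path

                d = Path(out_dir)
                d.mkdir(parents=True, exist_ok=True)
                stem = f"{arm}_{ipd.endpoint.lower()}"
                curve.to_csv(d / f"{stem}_curve.csv")
                risk.to_csv(d / f"{stem}_risk.csv")
                ipd.to_pseudo().to_csv(d / f"{stem}_ipd.csv")
    return out
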