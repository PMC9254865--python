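"""Validated model configuration (YAML/JSON) for the full pipeline.

The configuration mirrors the published input table: drug prices and dosing
units, subsequent-therapy costs and proportions, follow-up / management /
supportive-care items, utilities, the discount rate, and per-strategy curve
sources (direct parametric specs, median or life-year calibrations, hazard
ratios on another arm, or fits to digitized-curve CSVs). Unknown keys are
rejected and violations are reported with field paths.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ModelConfig", "load_and_validate", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridCfg(_Strict):
    cycle_length_days: float = Field(21.0, gt=0)
    horizon_years: float = Field(5.0, gt=0)


class OralDrugCfg(_Strict):
    name: str
    unit_price: float = Field(ge=0)
    units_per_day: float = Field(ge=0)
    dosed_fraction: float = Field(1.0, gt=0, le=1)


class InfusionCfg(_Strict):
    name: str
    price_per_unit: float = Field(ge=0)
    units_per_cycle: float = Field(ge=0)


class AEIncidenceCfg(_Strict):
    name: str
    incidence: float = Field(ge=0, le=1)


class CurveCfg(_Strict):
    """One endpoint's survival-curve source."""

    source: Literal[
        "parametric", "weibull_median", "exponential_discounted_ly", "hazard_ratio", "fit"
    ]
    # parametric
    family: Optional[str] = None
    params: Optional[dict[str, float]] = None
    # weibull_median
    median_months: Optional[float] = Field(None, gt=0)
    shape: Optional[float] = Field(None, gt=0)
    # exponential_discounted_ly
    target_discounted_ly: Optional[float] = Field(None, gt=0)
    # hazard_ratio
    reference: Optional[str] = None
    hr: Optional[float] = Field(None, gt=0)
    # fit
    curve_csv: Optional[str] = None
    risk_csv: Optional[str] = None
    criterion: Literal["aic", "bic"] = "aic"
    total_events: Optional[int] = Field(None, ge=0)

    @model_validator(mode="after")
    def _check_source_fields(self) -> "CurveCfg":
        need = {
            "parametric": ("family", "params"),
            "weibull_median": ("median_months", "shape"),
            "exponential_discounted_ly": ("target_discounted_ly",),
            "hazard_ratio": ("reference", "hr"),
            "fit": ("curve_csv", "risk_csv"),
        }[self.source]
        for f in need:
            if getattr(self, f) is None:
                raise ValueError(f"curve source {self.source!r} requires field {f!r}")
        return self


class StrategyCfg(_Strict):
    reference: bool = False
    oral: list[OralDrugCfg] = Field(default_factory=list)
    infusion: list[InfusionCfg] = Field(default_factory=list)
    subsequent_cost_per_cycle: float = Field(0.0, ge=0)
    subsequent_proportion: float = Field(0.0, ge=0, le=1)
    discontinuation_prob_ae: float = Field(0.0, ge=0, le=1)
    u_pfs: float = Field(ge=0, le=1)
    u_pd: float = Field(ge=0, le=1)
    ae_incidence: list[AEIncidenceCfg] = Field(default_factory=list)
    curves: dict[Literal["pfs", "os"], CurveCfg]

    @model_validator(mode="after")
    def _check_curves(self) -> "StrategyCfg":
        if set(self.curves) != {"pfs", "os"}:
            raise ValueError("curves must define both 'pfs' and 'os'")
        return self


class SharedCfg(_Strict):
    followup_cost_per_cycle: dict[str, float] = Field(default_factory=dict)
    management_cost_per_cycle: dict[str, float] = Field(default_factory=dict)
    ae_unit_costs: dict[str, float] = Field(default_factory=dict)
    bsc_cost_per_cycle: float = Field(0.0, ge=0)
    terminal_care_cost: float = Field(0.0, ge=0)
    ae_disutility: float = Field(0.0, ge=0)
    ae_duration_weeks: float = Field(4.0, gt=0)

    @model_validator(mode="after")
    def _nonnegative_items(self) -> "SharedCfg":
        for group in ("followup_cost_per_cycle", "management_cost_per_cycle", "ae_unit_costs"):
            for key, val in getattr(self, group).items():
                if val < 0:
                    raise ValueError(f"shared.{group}.{key} must be >= 0")
        return self


class ParameterCfg(_Strict):
    name: str
    base: float
    low: float
    high: float
    distribution: Literal["gamma", "beta", "fixed"]
    paths: list[str] = Field(min_length=1)


class PSACfg(_Strict):
    n_iter: int = Field(10_000, ge=1)
    wtp_max: float = Field(1_000_000.0, gt=0)
    wtp_step: float = Field(10_000.0, gt=0)


class ScenarioCfg(_Strict):
    horizons_years: list[float] = Field(default_factory=lambda: [5.0, 10.0, 20.0])
    price_parameter: str = "price_pembrolizumab_per_mg"
    price_reductions: list[float] = Field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75])


class SubgroupCfg(_Strict):
    label: str
    hr_pfs: float = Field(gt=0)
    hr_os: float = Field(gt=0)
    comparator: Optional[str] = None


class SimulateCfg(_Strict):
    """Synthetic-trial block; arms must match the strategy names."""

    n_per_arm: int = Field(355, ge=1)
    accrual_months: float = Field(12.0, ge=0)
    max_followup_months: float = Field(36.0, gt=0)
    pfs_weibull_shape: float = Field(1.2, gt=0)
    risk_grid_step_months: float = Field(3.0, gt=0)
    pfs_median_months: dict[str, float] = Field(default_factory=dict)


class ModelConfig(_Strict):
    """Root configuration for the cost-utility analysis."""

    grid: GridCfg = Field(default_factory=GridCfg)
    discount_rate: float = Field(0.05, ge=0, le=1)
    gdp_per_capita: float = Field(217_341.0, gt=0)
    strategies: dict[str, StrategyCfg]
    shared: SharedCfg = Field(default_factory=SharedCfg)
    parameters: list[ParameterCfg] = Field(default_factory=list)
    psa: PSACfg = Field(default_factory=PSACfg)
    scenarios: ScenarioCfg = Field(default_factory=ScenarioCfg)
    subgroups: list[SubgroupCfg] = Field(default_factory=list)
    simulate: Optional[SimulateCfg] = None

    @property
    def wtp_thresholds(self) -> tuple[float, float]:
        """1x and 3x GDP per capita."""
        return (self.gdp_per_capita, 3.0 * self.gdp_per_capita)

    @property
    def reference(self) -> str:
        return next(n for n, s in self.strategies.items() if s.reference)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        refs = [n for n, s in self.strategies.items() if s.reference]
        if len(refs) != 1:
            raise ValueError(f"exactly one reference strategy required, found {len(refs)}")
        if len(self.strategies) < 2:
            raise ValueError("need at least two strategies")
        for name, s in self.strategies.items():
            for ep, c in s.curves.items():
                if c.source == "hazard_ratio" and c.reference not in self.strategies:
                    raise ValueError(
                        f"strategies.{name}.curves.{ep}: hazard_ratio reference "
                        f"{c.reference!r} is not a strategy"
                    )
            for ae in s.ae_incidence:
                if ae.name not in self.shared.ae_unit_costs:
                    raise ValueError(
                        f"strategies.{name}: no shared.ae_unit_costs entry for {ae.name!r}"
                    )
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        if self.discount_rate > 0.08:
            warnings.warn(
                "discount_rate outside the conventional 0-8% band", stacklevel=2
            )
        return self


def load_and_validate(path) -> ModelConfig:
    """Load a YAML or JSON config file and validate every invariant."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelConfig.model_validate(raw)


def dump_config(cfg: ModelConfig, path=None) -> str:
    """Serialize a config back to YAML (round-trips through load)."""
    text = yaml.safe_dump(cfg.model_dump(exclude_none=True), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
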