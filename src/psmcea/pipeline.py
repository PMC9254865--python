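"""End-to-end pipeline: simulate -> reconstruct -> fit -> trace -> analyses.

One seed governs all stochastic stages through named substreams (simulate,
psa) so a run is reproducible from a single flag. Every artifact is plain
text (CSV/JSON) and the run log records package versions, the seed, and a
hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, dump_config
from .model import PartitionedSurvivalModel
from .reconstruct import km_estimate, reconstruct_ipd
from .synthetic import CLEAR_LIKE_SUMMARY, TrialSummary, generate_trial_artifacts

log = logging.getLogger("psmcea")

__all__ = ["run_pipeline", "substream_seed"]


def substream_seed(seed: int, stream: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _summary_from_config(cfg: ModelConfig) -> TrialSummary:
    sim = cfg.simulate
    base = CLEAR_LIKE_SUMMARY
    arms = tuple(cfg.strategies)
    pfs_hr, os_hr = {}, {}
    for name, s in cfg.strategies.items():
        pfs_c, os_c = s.curves["pfs"], s.curves["os"]
        pfs_hr[name] = pfs_c.hr if pfs_c.source == "hazard_ratio" else 1.0
        os_hr[name] = os_c.hr if os_c.source == "hazard_ratio" else 1.0
    ref_os = cfg.strategies[cfg.reference].curves["os"]
    anchor = {
        "discounted_ly": ref_os.target_discounted_ly or base.os_anchor["discounted_ly"],
        "horizon_years": cfg.grid.horizon_years,
        "discount_rate": cfg.discount_rate,
    }
    return TrialSummary(
        arm_names=arms,
        reference=cfg.reference,
        n_per_arm=sim.n_per_arm,
        pfs_median_months=dict(sim.pfs_median_months),
        pfs_hr_vs_ref=pfs_hr,
        os_hr_vs_ref=os_hr,
        os_anchor=anchor,
        accrual_months=sim.accrual_months,
        max_followup_months=sim.max_followup_months,
        pfs_weibull_shape=sim.pfs_weibull_shape,
    )


def run_pipeline(cfg: ModelConfig, seed: int, out_dir,
                 psa_n_iter: int | None = None) -> dict:
    """Execute every configured stage and write all artifacts to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = dump_config(cfg)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]

    import psmcea

    (out / "run.log").write_text(
        f"psmcea {psmcea.__version__}\nnumpy {np.__version__}\npandas {pd.__version__}\n"
        f"seed {seed}\nconfig_sha256 {cfg_hash}\n"
    )
    (out / "config.yaml").write_text(cfg_text)

    stage = "simulate"
    try:
        if cfg.simulate is not None:
            summary = _summary_from_config(cfg)
            sim_dir = out / "simulated"
            artifacts = generate_trial_artifacts(
                summary,
                seed=substream_seed(seed, "simulate"),
                risk_grid_step_months=cfg.simulate.risk_grid_step_months,
                out_dir=sim_dir,
            )
            stage = "reconstruct"
            for arm, endpoints in artifacts.items():
                for ep, art in endpoints.items():
                    ipd = reconstruct_ipd(art["curve"], art["risk"])
                    ipd.to_csv(sim_dir / f"{arm}_{ep.lower()}_reconstructed_ipd.csv")
                    km_estimate(ipd).to_csv(
                        sim_dir / f"{arm}_{ep.lower()}_reconstructed_km.csv"
                    )

        stage = "base_case"
        model = PartitionedSurvivalModel(cfg)
        res = model.fit()
        results = {
            "reference": res.reference,
            "wtp_thresholds": list(cfg.wtp_thresholds),
            "strategies": {
                n: {"cost": r.cost, "qaly": r.qaly, "ly": r.ly,
                    "cost_breakdown": res.breakdowns[n].as_dict()}
                for n, r in res.strategy_results.items()
            },
            "incremental": [
                {"comparator": r.comparator, "delta_cost": r.delta_cost,
                 "delta_qaly": r.delta_qaly,
                 "icer": r.icer if r.icer is not None else None, "label": r.label}
                for r in res.icer_table()
            ],
        }
        (out / "results.json").write_text(json.dumps(results, indent=2))
        for n, trace in res.traces.items():
            trace.to_csv(out / f"trace_{n}.csv")

        stage = "one_way_dsa"
        res.tornado_frame().to_csv(out / "tornado.csv", index=False)

        stage = "psa"
        psa = res.run_psa(n_iter=psa_n_iter, seed=substream_seed(seed, "psa"))
        psa.samples.to_csv(out / "psa_samples.csv", index=False)
        psa.ceac.to_csv(out / "ceac.csv", index=False)
        (out / "psa_quadrants.json").write_text(json.dumps(psa.quadrants, indent=2))

        stage = "scenarios"
        (out / "scenarios.json").write_text(json.dumps(res.scenarios(), indent=2))

        stage = "subgroups"
        (out / "subgroups.json").write_text(json.dumps(res.subgroups(), indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log.info("pipeline complete: %s", out)
    return results
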