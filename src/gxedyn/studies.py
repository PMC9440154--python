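"""Replication drivers for the four simulation studies.

* Study 1 — gene finding: GWAS scans of cohorts generated under increasing
  GxE strength (almost linear gamma = 0.05, moderately nonlinear 0.20,
  highly nonlinear 0.35, all with alpha = 0.05); Bonferroni hit counts,
  cumulative R^2, and QQ data.
* Study 2 — risk prediction: cross-validated polygenic-score curves on the
  same three conditions.
* Study 3 — heritability vs nonlinearity: GREML estimates as gamma grows
  from 0 to 0.2 with a single weak static environmental factor
  (epsilon = 0.01, N_e = 1).
* Study 4 — heritability vs relatedness: GREML on samples of relative pairs
  (relatedness 0 to 1) sharing environmental dynamics and GxE assignments,
  with gamma fixed at 0.2.

Each driver runs at the studies' reference sample sizes by default
(study 1/2: n = 10,000; study 3: n = 2,000; study 4: 1,000 pairs) and
accepts a proportional ``scale`` for desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gcta, gwas, prs
from .config import SimulationConfig
from .dynamics import stabilization_ratios
from .population import simulate_cohort

STUDY1_GAMMAS = {"almost_linear": 0.05, "moderately_nonlinear": 0.20, "highly_nonlinear": 0.35}
STUDY3_GAMMA_GRID = (0.0, 0.05, 0.10, 0.15, 0.20)
STUDY4_RELATEDNESS_GRID = (0.0, 0.125, 0.25, 0.5, 1.0)


def study3_config(**overrides) -> SimulationConfig:
    """Study-3/4 base configuration: one weak static attractor."""
    base = dict(alpha=0.05, epsilon=0.01, n_static=1)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class StudyReport:
    """Condition-level results of one study, with the config echo and seed."""

    study_id: str
    conditions: list[dict]
    config: SimulationConfig
    seed: int | None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.conditions)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary().to_csv(out / f"{self.study_id}_summary.tsv", sep="\t", index=False)
        for name, df in self.tables.items():
            df.to_csv(out / f"{self.study_id}_{name}.tsv", sep="\t", index=False)
        report = {
            "study_id": self.study_id,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "conditions": _jsonable(self.conditions),
        }
        (out / f"{self.study_id}_report.json").write_text(json.dumps(report, indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_study(
    study_id: str,
    seed: int | None = 0,
    scale: float = 1.0,
    overrides: dict | None = None,
    alpha_level: float = 0.05,
) -> StudyReport:
    """Execute one of the four study designs at its reference parameters.

    ``scale`` shrinks the sample size proportionally (statistics such as hit
    counts are sample-size dependent and will shrink with it); ``overrides``
    are applied to the base configuration before anything is simulated.
    """
    if study_id not in ("study1", "study2", "study3", "study4"):
        raise ValueError(f"unknown study id {study_id!r}")
    if not 0 < scale <= 1.0:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    overrides = overrides or {}

    if study_id in ("study1", "study2"):
        cfg = SimulationConfig(**overrides)
        n = max(100, int(round(10_000 * scale)))
        conditions = []
        tables: dict[str, pd.DataFrame] = {}
        for name, g in STUDY1_GAMMAS.items():
            cohort = simulate_cohort(cfg.replace(gamma=g), n, seed)
            res = gwas.gwas_scan(cohort)
            if study_id == "study1":
                hits = gwas.bonferroni_hits(res, alpha_level)
                cum = gwas.cumulative_r2(res, by="index")
                ratios = stabilization_ratios(cohort.p_series)
                ratios = ratios[np.isfinite(ratios)]
                conditions.append(
                    {
                        "condition": name,
                        "gamma": g,
                        "n": n,
                        "bonferroni_hits": int(hits.size),
                        "cumulative_r2_total": float(cum[-1]),
                        "stabilization_median": float(np.median(ratios)),
                        "stabilization_p75": float(np.percentile(ratios, 75)),
                    }
                )
                tables[f"{name}_scan"] = pd.DataFrame(
                    {
                        "snp": np.arange(1, res.n_snps + 1),
                        "beta": res.beta,
                        "se": res.se,
                        "r2": res.r2,
                        "pval": res.pval,
                        "cumulative_r2": cum,
                    }
                )
            else:
                train, test = prs.split_cohort(cohort, 0.5, seed)
                curve = prs.prs_curve(train, test, alpha=alpha_level)
                conditions.append(
                    {
                        "condition": name,
                        "gamma": g,
                        "n": n,
                        "peak_r2_test": curve.peak_r2_test,
                        "peak_k": curve.peak_k,
                        "final_r2_test": float(curve.r2_test[-1]),
                        "mean_r2_test": float(curve.r2_test.mean()),
                    }
                )
                tables[f"{name}_prs"] = pd.DataFrame(
                    {
                        "k": curve.k,
                        "snp_added": curve.snp + 1,
                        "pval_train": curve.pval_train,
                        "r2_train": curve.r2_train,
                        "r2_test": curve.r2_test,
                        "significant": curve.sig_mask.astype(int),
                    }
                )
        return StudyReport(study_id, conditions, cfg, seed, tables)

    if study_id == "study3":
        cfg = study3_config(**overrides)
        n = max(100, int(round(2000 * scale)))
        table = gcta.h2_vs_gamma(STUDY3_GAMMA_GRID, n, cfg, seed)
        conditions = table.assign(n=n).to_dict("records")
        return StudyReport("study3", conditions, cfg, seed, {"h2_vs_gamma": table})

    cfg = study3_config(**{"gamma": 0.2, **overrides})
    n_pairs = max(50, int(round(1000 * scale)))
    table = gcta.h2_vs_relatedness(STUDY4_RELATEDNESS_GRID, n_pairs, cfg, seed)
    conditions = table.assign(n_pairs=n_pairs).to_dict("records")
    return StudyReport("study4", conditions, cfg, seed, {"h2_vs_relatedness": table})
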