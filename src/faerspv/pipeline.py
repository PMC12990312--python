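"""End-to-end pharmacovigilance run: generate or load reports, ingest and
deduplicate, detect signals, run the regression cascade, profile time to
onset, and write tabular artifacts with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ingest as fi
from . import regression as rg
from . import signals as sg
from . import synthetic as sy
from . import tto

logger = logging.getLogger(__name__)

DEFAULT_TARGET_PTS = ("Proteinuria",)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    mode: str = "synthetic"                 # "synthetic" | "faers_dir"
    faers_dir: str | None = None
    n_reports: int = 60000
    target_pts: Sequence[str] = DEFAULT_TARGET_PTS
    screen_min_a: int = 100
    screen_alpha: float = 0.01
    screen_ror_rule: str = "ci_lower"
    lambda_rule: str = "1se"
    lasso_folds: int = 10
    multivariate_alpha: float = 0.01
    ic_mode: str = "mle"
    zero_correction: bool = False
    include_imprecise_tto: bool = False
    seed: int = 0
    criteria: sg.SignalCriteria = field(default_factory=sg.SignalCriteria)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "faers_dir"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "faers_dir" and not self.faers_dir:
            raise ValueError("faers_dir mode needs a directory")
        if self.screen_min_a <= 0 or self.screen_alpha <= 0:
            raise ValueError("screen thresholds must be positive")
        if not self.target_pts:
            raise ValueError("target_pts is empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        criteria = payload.pop("criteria", None)
        cfg = cls(**payload)
        if criteria:
            cfg.criteria = sg.SignalCriteria(**criteria)
        cfg.validate()
        return cfg

    def as_dict(self) -> dict:
        out = asdict(self)
        out["target_pts"] = list(self.target_pts)
        return out


# ---------------------------------------------------------------------------
# baseline summary

AGE_BINS = (("<18", 0, 18), ("18-64", 18, 65), ("65-85", 65, 86), (">85", 86, 1e9))
WEIGHT_BINS = (("<25", 0, 25), ("25-50", 25, 51), ("51-75", 51, 76), (">76", 76, 1e9))
YEAR_BINS = (("2004-2008", 2004, 2008), ("2009-2012", 2009, 2012),
             ("2013-2016", 2013, 2016), ("2017-2020", 2017, 2020),
             ("2021-2024", 2021, 2024))


def component_ratio(count: int, total: int) -> float:
    """A category's share of the target-event cases, as a percentage to 2 dp."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def summarize_baseline(store: fi.CaseStore, target_pts: Sequence[str] = DEFAULT_TARGET_PTS,
                       top_countries: int = 5) -> pd.DataFrame:
    """Baseline characteristics of the target-event cases.

    Counts and component ratios (percent of all target-event cases, two
    decimals) across sex, age bins, weight bins, reporting-year bins, and
    the top reporting countries plus "Others".  Raises on an empty store.
    """
    event_pids = store.event_primaryids(target_pts)
    demo = store.demo[store.demo["primaryid"].isin(event_pids)]
    total = len(demo)
    if total == 0:
        raise ValueError("no target-event cases to summarize")
    rows: list[dict] = []

    def add(section, category, count):
        rows.append({"characteristic": section, "category": category,
                     "n": int(count), "component_ratio": component_ratio(count, total)})

    add("sex", "Male", (demo["sex"] == "male").sum())
    add("sex", "Female", (demo["sex"] == "female").sum())
    add("sex", "Missing", (demo["sex"] == "missing").sum())

    age = demo["age_years"]
    for label, lo, hi in AGE_BINS:
        add("age", label, ((age >= lo) & (age < hi)).sum())
    add("age", "Missing", age.isna().sum())

    wt = demo["weight_kg"]
    for label, lo, hi in WEIGHT_BINS:
        add("weight_kg", label, ((wt >= lo) & (wt < hi)).sum())
    add("weight_kg", "Missing", wt.isna().sum())

    year = demo["receipt_date"].dt.year
    for label, lo, hi in YEAR_BINS:
        add("reporting_year", label, ((year >= lo) & (year <= hi)).sum())

    country = demo["country"].replace("missing", np.nan).dropna()
    counts = country.value_counts()
    for name, n in counts.head(top_countries).items():
        add("country", name, n)
    add("country", "Others", total - int(counts.head(top_countries).sum()))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

def _acquire_store(config: RunConfig, outdir: Path
                   ) -> tuple[fi.CaseStore, sy.GroundTruth | None]:
    if config.mode == "faers_dir":
        return fi.load_faers_directory(config.faers_dir), None
    syn_cfg = sy.default_config(n_reports=config.n_reports, seed=config.seed)
    tables, truth = sy.generate_reports(syn_cfg)
    truth.to_json(outdir / "ground_truth.json")
    store = fi.build_store(tables)
    return store, truth


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the whole pipeline and write artifacts under ``outdir``.

    Artifacts: ``baseline.csv``, ``signals.csv``, ``prior.json``,
    ``univariate.csv``, ``lasso_path.csv``, ``forest.csv``, ``roc.csv``,
    ``tto_summary.csv``, ``tto_ecdf.csv``, ``summary.json`` and
    ``manifest.json`` (plus ``ground_truth.json`` and a ground-truth
    comparison in synthetic mode).  Identical config and seed give
    byte-identical outputs.  Any stage failure raises with the stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "acquire"
    summary: dict = {}
    try:
        store, truth = _acquire_store(config, outdir)
        logger.info("ingest: %d cases retained, %d duplicate versions removed",
                    store.log.cases_retained, store.log.duplicates_removed)
        summary["n_cases"] = store.n_cases
        summary["ingest_log"] = store.log.as_dict()

        stage = "baseline"
        baseline = summarize_baseline(store, config.target_pts)
        baseline.to_csv(outdir / "baseline.csv", index=False)

        stage = "signals"
        tables2x2 = sg.contingency_all(store, config.target_pts)
        pairs = tables2x2[tables2x2["a"] + tables2x2["b"] > 0]
        expected = (pairs["a"] + pairs["b"]) * (pairs["a"] + pairs["c"]) / store.n_cases
        prior = sg.fit_mgps_hyperprior(pairs["a"].to_numpy(),
                                       expected.to_numpy(), seed=config.seed)
        (outdir / "prior.json").write_text(json.dumps(prior.as_dict(), indent=1))
        sig = sg.signal_table(pairs, prior=prior, criteria=config.criteria,
                              ic_mode=config.ic_mode)
        sig.sort_values("a", ascending=False).to_csv(outdir / "signals.csv",
                                                     float_format="%.6g")
        summary["n_consensus_signals"] = int(sig["consensus"].sum())
        summary["consensus_drugs"] = sorted(sig.index[sig["consensus"]])

        stage = "regression"
        dm = rg.build_design_matrix(store, list(sig.index), config.target_pts)
        screen = rg.univariate_screen(dm, sig, min_a=config.screen_min_a,
                                      alpha=config.screen_alpha,
                                      ror_rule=config.screen_ror_rule)
        screen.per_drug.to_csv(outdir / "univariate.csv", float_format="%.6g")
        summary["n_screen_retained"] = len(screen.retained)
        if len(screen.retained) >= 2:
            lasso = rg.lasso_select(dm, screen.retained, n_folds=config.lasso_folds,
                                    rule=config.lambda_rule, seed=config.seed)
            lasso.path.to_csv(outdir / "lasso_path.csv", index=False,
                              float_format="%.6g")
            selected = lasso.selected
            summary["lambda_chosen"] = lasso.lambda_chosen
        else:
            selected = list(screen.retained)
            pd.DataFrame(columns=["lambda", "mean_deviance", "se_deviance",
                                  "n_nonzero"]).to_csv(
                outdir / "lasso_path.csv", index=False)
        summary["n_lasso_selected"] = len(selected)
        if selected:
            mv = rg.multivariate_fit(dm, selected, alpha=config.multivariate_alpha)
            mv.terms.to_csv(outdir / "forest.csv", float_format="%.6g")
            probs = rg.predicted_probabilities(dm, mv, selected)
            auc, roc = rg.roc_auc(probs, dm.y.to_numpy())
            roc.to_csv(outdir / "roc.csv", index=False, float_format="%.6g")
            summary["significant_drugs"] = mv.significant_drugs
            summary["auc"] = auc
        else:
            summary["significant_drugs"] = []
            summary["auc"] = None

        stage = "tto"
        records = tto.onset_records(store, config.target_pts,
                                    include_imprecise=config.include_imprecise_tto)
        tto.class_tto_summary(records).to_csv(outdir / "tto_summary.csv",
                                              float_format="%.6g")
        if len(records):
            tto.cumulative_incidence(records).to_csv(
                outdir / "tto_ecdf.csv", index=False, float_format="%.6g")

        if truth is not None:
            stage = "ground_truth_comparison"
            comparison = _compare_with_truth(sig, summary, truth)
            (outdir / "ground_truth_comparison.json").write_text(
                json.dumps(comparison, indent=1, sort_keys=True))
            summary["ground_truth_comparison"] = comparison
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str))
    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "config": config.as_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary


def _compare_with_truth(sig: pd.DataFrame, summary: dict,
                        truth: sy.GroundTruth) -> dict:
    planted = {d for d, th in truth.theta.items() if th > 1.0}
    flagged = set(sig.index[sig["consensus"]])
    return {
        "planted_signals": sorted(planted),
        "consensus_flagged": sorted(flagged),
        "true_positives": sorted(planted & flagged),
        "false_positives": sorted(flagged - planted),
        "false_negatives": sorted(planted - flagged),
        "significant_drugs": summary.get("significant_drugs", []),
    }
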