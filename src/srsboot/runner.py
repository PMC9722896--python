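"""Study orchestration: run configured experiment suites and replicate
error metrics from serialized probability tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, generate_cohort, read_cohort
from .engine import EngineConfig, ExperimentResult, run_experiment
from .errors import ConfigurationError, SchemaError
from .importance import aggregate_experiment_importance
from .metrics import ErrorMetrics, compute_error_metrics
from .stratify import (
    all_scanner_pairs,
    run_scanner_pair_experiment,
    site_groups,
    stratified_metrics,
    volume_groups,
)
from .volume_filter import (
    SWEEP_THRESHOLDS,
    decisions_frame,
    select_features_for_removal,
    threshold_sweep,
)

logger = logging.getLogger(__name__)

PROBABILITY_COLUMNS = ["rep", "bm_id", "partition", "probability", "label"]
VALID_EXPERIMENTS = (
    "feature_sets",
    "stratify_site",
    "stratify_volume",
    "volume_sweep",
    "scanner_pairs",
    "importance",
)


@dataclass
class StudyConfig:
    cohort_path: str | None = None  # delimited feature table; None -> synthetic
    cohort: CohortConfig = field(default_factory=CohortConfig)
    experiments: list[str] = field(default_factory=lambda: ["feature_sets"])
    engine: EngineConfig = field(default_factory=EngineConfig)
    volume_threshold: float = 1.0
    sweep_thresholds: tuple[float, ...] = SWEEP_THRESHOLDS
    out_dir: str = "study_out"
    seed: int = 0

    def validate(self) -> None:
        if not self.experiments:
            raise ConfigurationError("experiment list is empty")
        unknown = [e for e in self.experiments if e not in VALID_EXPERIMENTS]
        if unknown:
            raise ConfigurationError(f"unknown experiments: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("cohort_path", "experiments", "volume_threshold", "out_dir", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "sweep_thresholds" in raw:
            cfg.sweep_thresholds = tuple(raw["sweep_thresholds"])
        for key, val in raw.get("engine", {}).items():
            if not hasattr(cfg.engine, key):
                raise ConfigurationError(f"unknown engine option {key!r}")
            setattr(cfg.engine, key, val)
        for key, val in raw.get("cohort", {}).items():
            if not hasattr(cfg.cohort, key):
                raise ConfigurationError(f"unknown cohort option {key!r}")
            setattr(cfg.cohort, key, val)
        return cfg


def _metrics_table(metrics: dict[str, ErrorMetrics | None]) -> pd.DataFrame:
    rows = []
    for stratum, m in metrics.items():
        if m is None:
            rows.append(
                {"metric": "auc", "estimate": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "stratum": stratum}
            )
            continue
        rows.extend(m.to_rows())
    return pd.DataFrame(rows)


def _experiment_metrics(exp: ExperimentResult, stratum: str = "overall") -> ErrorMetrics:
    tp, ty = exp.pooled("test")
    op, oy = exp.pooled("oob")
    ap, ay = exp.pooled("apparent")
    return compute_error_metrics(
        tp, ty, op, oy, ap, ay,
        per_rep=exp.per_rep("test"),
        per_rep_apparent=exp.per_rep("apparent"),
        stratum=stratum,
    )


def run_study(config: StudyConfig) -> dict:
    """Execute the configured experiments; write tables and a run log."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "experiments": [], "decisions": []}

    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        log["cohort"] = {"source": config.cohort_path}
    else:
        config.cohort.seed = config.cohort.seed or config.seed
        cohort = generate_cohort(config.cohort)
        log["cohort"] = {"source": "synthetic", "seed": config.cohort.seed}
    log["cohort"]["n_bms"] = cohort.n_bms
    log["cohort"]["prevalence"] = float(cohort.labels.mean())

    removed: set[str] = set()
    if config.volume_threshold < 1.0:
        removed, decisions = select_features_for_removal(
            cohort, threshold=config.volume_threshold
        )
        decisions_frame(decisions).to_csv(out / "filter_decisions.tsv", sep="\t", index=False)
        log["decisions"].append(
            f"volume filter at {config.volume_threshold}: removed {len(removed)} features"
        )

    bundle: dict = {"cohort": cohort, "log": log}
    both_exp: ExperimentResult | None = None

    def _get_both() -> ExperimentResult:
        nonlocal both_exp
        if both_exp is None:
            both_exp = run_experiment(
                cohort, "both", removed_features=removed,
                seed=config.seed, config=config.engine,
            )
        return both_exp

    for name in config.experiments:
        logger.info("running experiment %s", name)
        if name == "feature_sets":
            tables = []
            for fs in ("clinical", "radiomic", "both"):
                exp = (
                    _get_both()
                    if fs == "both"
                    else run_experiment(
                        cohort, fs, removed_features=removed,
                        seed=config.seed, config=config.engine,
                    )
                )
                exp.to_table().to_csv(
                    out / f"probabilities_{fs}.tsv", sep="\t", index=False
                )
                m = _experiment_metrics(exp, stratum=fs)
                tables.append(_metrics_table({fs: m}))
            pd.concat(tables).to_csv(out / "feature_set_metrics.tsv", sep="\t", index=False)
        elif name == "stratify_site":
            table = _metrics_table(
                stratified_metrics(_get_both(), site_groups(cohort), cohort=cohort)
            )
            table.to_csv(out / "site_metrics.tsv", sep="\t", index=False)
        elif name == "stratify_volume":
            table = _metrics_table(
                stratified_metrics(_get_both(), volume_groups(cohort), cohort=cohort)
            )
            table.to_csv(out / "volume_metrics.tsv", sep="\t", index=False)
        elif name == "volume_sweep":
            sweep = threshold_sweep(
                cohort, thresholds=config.sweep_thresholds,
                engine_config=config.engine, seed=config.seed,
            )
            rows = []
            for t in sweep.thresholds:
                for stratum, m in sweep.metrics[t].items():
                    if m is None:
                        continue
                    for row in m.to_rows():
                        row["threshold"] = t
                        rows.append(row)
            pd.DataFrame(rows).to_csv(out / "sweep_metrics.tsv", sep="\t", index=False)
            bundle["sweep"] = sweep
        elif name == "scanner_pairs":
            rows = []
            for pair in all_scanner_pairs():
                try:
                    m, _ = run_scanner_pair_experiment(
                        cohort, pair, engine_config=config.engine, seed=config.seed
                    )
                except Exception as exc:  # insufficient subset: report and continue
                    log["decisions"].append(f"scanner pair {pair} skipped: {exc}")
                    continue
                rows.extend(m.to_rows())
            pd.DataFrame(rows).to_csv(out / "scanner_pair_metrics.tsv", sep="\t", index=False)
        elif name == "importance":
            report = aggregate_experiment_importance(_get_both())
            report.to_frame().to_csv(out / "importance.tsv", sep="\t", index=False)
            bundle["importance"] = report
        log["experiments"].append(name)

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    bundle["out_dir"] = str(out)
    return bundle


# ---------------------------------------------------------------------------
# Replication from serialized probabilities


def read_probability_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"probability table missing columns: {missing}")
    bad = df.index[
        ~df["partition"].isin(["test", "oob", "apparent"])
        | ~df["probability"].between(0, 1)
        | ~df["label"].isin([0, 1])
    ]
    if len(bad):
        raise SchemaError(f"invalid probability-table rows at lines {list(bad[:5])}")
    return df


def replicate_error_metrics(
    table: pd.DataFrame,
    strata: pd.Series | None = None,
) -> dict[str, ErrorMetrics | None]:
    """Recompute the metric suite from a (rep, bm_id, partition, probability,
    label) table without refitting any model.
    """
    for part in ("test", "oob"):
        if not (table["partition"] == part).any():
            raise SchemaError(f"probability table has no {part!r} rows")

    def pool(part: str, mask=None) -> tuple[np.ndarray, np.ndarray]:
        sub = table[table["partition"] == part]
        if mask is not None:
            sub = sub[sub["bm_id"].map(mask).to_numpy()]
        return sub["probability"].to_numpy(), sub["label"].to_numpy(dtype=int)

    def per_rep(part: str):
        sub = table[table["partition"] == part]
        return [
            (g["probability"].to_numpy(), g["label"].to_numpy(dtype=int))
            for _, g in sub.groupby("rep")
        ]

    has_apparent = (table["partition"] == "apparent").any()
    results: dict[str, ErrorMetrics | None] = {
        "overall": compute_error_metrics(
            *pool("test"),
            *pool("oob"),
            *(pool("apparent") if has_apparent else (None, None)),
            per_rep=per_rep("test"),
            per_rep_apparent=per_rep("apparent") if has_apparent else None,
        )
    }
    if strata is not None:
        for grp in strata.unique():
            in_group = (strata == grp).to_dict()
            tp, ty = pool("test", in_group)
            op, oy = pool("oob", in_group)
            if len(np.unique(ty)) < 2 or len(np.unique(oy)) < 2:
                results[str(grp)] = None
                continue
            ap, ay = pool("apparent", in_group) if has_apparent else (None, None)
            results[str(grp)] = compute_error_metrics(
                tp, ty, op, oy, ap, ay, stratum=str(grp)
            )
    return results
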