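"""Stratum-wise re-aggregation of pooled predictions and scanner subsets.

Pooled test / out-of-bag / resubstitution probabilities are partitioned
by a per-lesion grouping (primary site, volume group at the 7.5 cc cut,
or scanner model) and the full metric suite is recomputed per group.  By
default the operating point is re-derived from each group's own pooled
out-of-bag probabilities; a global-threshold mode is available.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import Cohort, MAJOR_SCANNER_MODELS, scanner_model
from .engine import EngineConfig, ExperimentResult, run_experiment
from .errors import InsufficientDataError, UndefinedMetricError
from .metrics import ErrorMetrics, compute_error_metrics

logger = logging.getLogger(__name__)

VOLUME_CUT_CC = 7.5


def volume_groups(cohort: Cohort, cut: float = VOLUME_CUT_CC) -> pd.Series:
    """"small"/"large" per lesion at the volume cut, indexed by bm_id."""
    labels = np.where(cohort.volumes < cut, "small", "large")
    return pd.Series(labels, index=cohort.df["bm_id"].to_numpy(), name="volume_group")


def site_groups(cohort: Cohort) -> pd.Series:
    return pd.Series(
        cohort.df["primary_site"].to_numpy(),
        index=cohort.df["bm_id"].to_numpy(),
        name="primary_site",
    )


def scanner_groups(cohort: Cohort) -> pd.Series:
    models = [scanner_model(t) for t in cohort.df["scanner"]]
    return pd.Series(
        models, index=cohort.df["bm_id"].to_numpy(), name="scanner_model"
    )


def _grouped_pairs(exp: ExperimentResult, groups: pd.Series, partition: str):
    """group -> (probs, labels) pooled across repetitions, restricted to group."""
    out: dict[str, list] = {}
    for r in exp.repetitions:
        if partition == "test":
            ids, probs, labels = r.test_bm_ids, r.test_probs, r.test_labels
        elif partition == "oob":
            ok = np.isfinite(r.oob_probs)
            ids = [b for b, k in zip(r.train_bm_ids, ok) if k]
            probs, labels = r.oob_probs[ok], r.train_labels[ok]
        elif partition == "apparent":
            ids, probs, labels = r.train_bm_ids, r.apparent_probs, r.train_labels
        else:
            raise ValueError(partition)
        g = groups.loc[list(ids)].to_numpy()
        for grp in np.unique(g):
            sel = g == grp
            out.setdefault(grp, [[], []])
            out[grp][0].append(np.asarray(probs)[sel])
            out[grp][1].append(np.asarray(labels)[sel])
    return {
        k: (np.concatenate(v[0]), np.concatenate(v[1])) for k, v in out.items()
    }


def _grouped_per_rep(exp: ExperimentResult, groups: pd.Series, partition: str):
    out: dict[str, list] = {}
    for r in exp.repetitions:
        if partition == "test":
            ids, probs, labels = r.test_bm_ids, r.test_probs, r.test_labels
        else:
            ids, probs, labels = r.train_bm_ids, r.apparent_probs, r.train_labels
        g = groups.loc[list(ids)].to_numpy()
        for grp in np.unique(g):
            sel = g == grp
            out.setdefault(grp, []).append(
                (np.asarray(probs)[sel], np.asarray(labels)[sel])
            )
    return out


def stratified_metrics(
    exp: ExperimentResult,
    groups: pd.Series,
    cohort: Cohort | None = None,
    per_stratum_operating_point: bool = True,
    min_stratum_size: int = 2,
) -> dict[str, ErrorMetrics | None]:
    """Full metric suite per group; ``None`` marks undefined (single-class) groups.

    The "overall" entry pools every group and reproduces the
    unstratified metrics exactly.
    """
    test = _grouped_pairs(exp, groups, "test")
    oob = _grouped_pairs(exp, groups, "oob")
    apparent = _grouped_pairs(exp, groups, "apparent")
    test_reps = _grouped_per_rep(exp, groups, "test")
    app_reps = _grouped_per_rep(exp, groups, "apparent")

    results: dict[str, ErrorMetrics | None] = {}
    tp, ty = exp.pooled("test")
    op_probs, op_labels = exp.pooled("oob")
    ap, ay = exp.pooled("apparent")
    results["overall"] = compute_error_metrics(
        tp, ty, op_probs, op_labels, ap, ay,
        per_rep=exp.per_rep("test"), per_rep_apparent=exp.per_rep("apparent"),
    )
    global_threshold = results["overall"].operating_point.threshold

    for grp in sorted(test):
        probs, labels = test[grp]
        if labels.size < min_stratum_size or len(np.unique(labels)) < 2:
            logger.warning("stratum %r undefined (single class or too small)", grp)
            results[str(grp)] = None
            continue
        o_probs, o_labels = oob.get(grp, (None, None))
        try:
            if per_stratum_operating_point and o_probs is not None and len(
                np.unique(o_labels)
            ) == 2:
                metrics = compute_error_metrics(
                    probs, labels, o_probs, o_labels, *apparent.get(grp, (None, None)),
                    per_rep=test_reps.get(grp),
                    per_rep_apparent=app_reps.get(grp),
                    stratum=str(grp),
                )
            else:
                from .metrics import (
                    MetricWithCI,
                    auc_632plus,
                    pooled_auc,
                    transfer_operating_point,
                )

                auc = pooled_auc(probs, labels)
                a_probs, a_labels = apparent.get(grp, (None, None))
                corrected = (
                    auc_632plus(pooled_auc(a_probs, a_labels), auc)
                    if a_probs is not None and len(np.unique(a_labels)) == 2
                    else float("nan")
                )
                mcr, fnr, fpr = transfer_operating_point(
                    global_threshold, probs, labels
                )
                metrics = ErrorMetrics(
                    auc=MetricWithCI(auc),
                    auc_632plus=MetricWithCI(corrected),
                    mcr=MetricWithCI(mcr),
                    fnr=MetricWithCI(fnr),
                    fpr=MetricWithCI(fpr),
                    operating_point=None,
                    n=int(labels.size),
                    prevalence=float(np.mean(labels)),
                    stratum=str(grp),
                )
            results[str(grp)] = metrics
        except UndefinedMetricError as exc:
            logger.warning("stratum %r undefined: %s", grp, exc)
            results[str(grp)] = None
    return results


def run_scanner_pair_experiment(
    cohort: Cohort,
    pair: tuple[str, str],
    engine_config: EngineConfig | None = None,
    feature_set: str = "both",
    seed: int = 0,
    n_reps: int | None = None,
    removed_features=(),
) -> tuple[ErrorMetrics, ExperimentResult]:
    """Subset the cohort to two scanner models and rerun the experiment."""
    models = np.array([scanner_model(t) for t in cohort.df["scanner"]])
    mask = np.isin(models, list(pair))
    sub = cohort.subset(mask)
    if sub.n_bms < 4 or len(np.unique(sub.labels)) < 2:
        raise InsufficientDataError(
            f"scanner pair {pair} leaves too little data ({sub.n_bms} lesions)"
        )
    exp = run_experiment(
        sub,
        feature_set=feature_set,
        n_reps=n_reps,
        removed_features=removed_features,
        seed=seed,
        config=engine_config,
    )
    tp, ty = exp.pooled("test")
    op, oy = exp.pooled("oob")
    ap, ay = exp.pooled("apparent")
    metrics = compute_error_metrics(
        tp, ty, op, oy, ap, ay,
        per_rep=exp.per_rep("test"),
        per_rep_apparent=exp.per_rep("apparent"),
        stratum="+".join(pair),
    )
    return metrics, exp


def all_scanner_pairs(models=MAJOR_SCANNER_MODELS):
    return list(combinations(models, 2))
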