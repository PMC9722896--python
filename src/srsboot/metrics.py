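"""ROC-based error metrics for pooled bootstrap predictions.

Implements the pooled ROC curve, AUC with percentile confidence
intervals, the .632+ bootstrap correction in AUC space, out-of-bag
operating-point selection (closest point to the upper-left corner) and
the transfer of that operating point to pooled test predictions to
obtain misclassification, false-negative and false-positive rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)

#: No-information error rate for a binary ranking statistic: a random
#: ranking has AUC 0.5, i.e. error 0.5.
NO_INFORMATION_ERROR = 0.5


@dataclass(frozen=True)
class ROCCurve:
    """An ROC curve as parallel FPR/TPR/threshold arrays.

    ``fpr`` and ``tpr`` are non-decreasing and bracketed by (0, 0) and
    (1, 1).  A point is reached by classifying ``prob >= threshold`` as
    positive; the (0, 0) endpoint carries threshold ``+inf``.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve coordinates must be non-decreasing")

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    fpr: float
    tpr: float


@dataclass
class MetricWithCI:
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.estimate, self.ci_low, self.ci_high)


@dataclass
class ErrorMetrics:
    """Full metric suite for one pooled set of predictions."""

    auc: MetricWithCI
    auc_632plus: MetricWithCI
    mcr: MetricWithCI
    fnr: MetricWithCI
    fpr: MetricWithCI
    operating_point: OperatingPoint | None = None
    n: int = 0
    prevalence: float = float("nan")
    stratum: str = "overall"
    extras: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for name in ("auc", "auc_632plus", "mcr", "fnr", "fpr"):
            m: MetricWithCI = getattr(self, name)
            rows.append(
                {
                    "metric": name,
                    "estimate": m.estimate,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "stratum": self.stratum,
                }
            )
        return rows


def _check_two_classes(labels: np.ndarray, stratum: str = "input") -> None:
    labels = np.asarray(labels)
    if labels.size == 0 or len(np.unique(labels)) < 2:
        raise UndefinedMetricError(
            f"both outcome classes required in {stratum!r} "
            f"(got classes {sorted(np.unique(labels).tolist())})"
        )


def pooled_roc(probabilities: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Threshold-sweep ROC over pooled (probability, label) pairs."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y, "pooled ROC input")
    fpr, tpr, thr = roc_curve(y, probs)
    # roc_curve already yields (0,0)..(1,1); thresholds[0] is +inf.
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def pooled_auc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Pooled AUC with midpoint (Mann-Whitney) tie handling."""
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y, "pooled AUC input")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def auc_632plus(apparent_auc: float, bootstrap_auc: float) -> float:
    """.632+ corrected AUC from apparent and out-of-sample bootstrap AUCs.

    Works in error space ``e = 1 - AUC`` with no-information error 0.5:
    the relative overfitting rate ``R = (e1 - e_app)/(0.5 - e_app)`` is
    clamped to [0, 1] (after clamping ``e1`` to at most 0.5) and the
    weight ``w = 0.632 / (1 - 0.368 R)`` blends the two error rates.
    """
    for name, v in (("apparent_auc", apparent_auc), ("bootstrap_auc", bootstrap_auc)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {v}")
    gamma = NO_INFORMATION_ERROR
    e_app = 1.0 - apparent_auc
    e1 = min(1.0 - bootstrap_auc, gamma)
    if e_app >= gamma:
        # Apparent error already at/beyond chance: no-overfit limit.
        logger.info("apparent error %.3f >= no-information 0.5; R set to 0", e_app)
        r = 0.0
    else:
        r = (e1 - e_app) / (gamma - e_app)
        r = min(max(r, 0.0), 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    corrected_error = (1.0 - w) * e_app + w * e1
    return 1.0 - corrected_error


def optimal_upper_left(curve: ROCCurve) -> OperatingPoint:
    """ROC point minimizing Euclidean distance to (FPR, TPR) = (0, 1).

    Ties are broken in favour of the lower FPR.
    """
    d2 = curve.fpr**2 + (1.0 - curve.tpr) ** 2
    best = np.min(d2)
    candidates = np.flatnonzero(np.isclose(d2, best))
    idx = candidates[np.argmin(curve.fpr[candidates])]
    return OperatingPoint(
        threshold=float(curve.thresholds[idx]),
        fpr=float(curve.fpr[idx]),
        tpr=float(curve.tpr[idx]),
    )


def transfer_operating_point(
    threshold: float,
    probabilities: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """Apply ``prob >= threshold`` to pooled pairs; return (MCR, FNR, FPR)."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y, "operating-point transfer input")
    pred = probs >= threshold
    pos = y == 1
    fn = int(np.sum(pos & ~pred))
    fp = int(np.sum(~pos & pred))
    tp = int(np.sum(pos & pred))
    tn = int(np.sum(~pos & ~pred))
    fnr = fn / (fn + tp)
    fpr = fp / (fp + tn)
    mcr = (fn + fp) / y.size
    return (mcr, fnr, fpr)


def percentile_ci(values: Sequence[float], level: float = 95.0) -> tuple[float, float]:
    """Empirical percentile interval of per-repetition statistics."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("at least two finite values required for a CI")
    tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(vals, [tail, 100.0 - tail])
    return (float(lo), float(hi))


def vertical_average_roc(
    curves: Sequence[ROCCurve],
    grid: np.ndarray | None = None,
    level: float = 95.0,
) -> dict[str, np.ndarray]:
    """Vertically average per-repetition ROC curves on a fixed FPR grid.

    Returns the grid, the mean TPR and the pointwise percentile band;
    used for plotting CI bands around the pooled curve.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    tprs = np.empty((len(curves), grid.size))
    for i, c in enumerate(curves):
        # Step interpolation: TPR at the largest curve FPR <= grid value.
        tprs[i] = np.interp(grid, c.fpr, c.tpr)
    tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(tprs, [tail, 100.0 - tail], axis=0)
    return {"fpr": grid, "tpr_mean": tprs.mean(axis=0), "tpr_low": lo, "tpr_high": hi}


def compute_error_metrics(
    test_probs: np.ndarray,
    test_labels: np.ndarray,
    oob_probs: np.ndarray,
    oob_labels: np.ndarray,
    apparent_probs: np.ndarray | None = None,
    apparent_labels: np.ndarray | None = None,
    per_rep: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    per_rep_apparent: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    stratum: str = "overall",
    ci_level: float = 95.0,
) -> ErrorMetrics:
    """Full metric suite from pooled test / out-of-bag / resubstitution pairs.

    The operating point is chosen on the pooled out-of-bag ROC curve and
    transferred to the pooled test pairs.  Confidence intervals are
    percentile intervals over per-repetition statistics when ``per_rep``
    (a sequence of per-repetition (probs, labels) test pools) is given.
    """
    test_labels = np.asarray(test_labels, dtype=int)
    _check_two_classes(test_labels, f"test pool of stratum {stratum!r}")
    auc = pooled_auc(test_probs, test_labels)

    if apparent_probs is not None and len(apparent_probs):
        apparent_auc = pooled_auc(apparent_probs, apparent_labels)
        corrected = auc_632plus(apparent_auc, auc)
    else:
        apparent_auc = float("nan")
        corrected = float("nan")

    oob_curve = pooled_roc(oob_probs, oob_labels)
    op = optimal_upper_left(oob_curve)
    mcr, fnr, fpr = transfer_operating_point(op.threshold, test_probs, test_labels)

    metrics = ErrorMetrics(
        auc=MetricWithCI(auc),
        auc_632plus=MetricWithCI(corrected),
        mcr=MetricWithCI(mcr),
        fnr=MetricWithCI(fnr),
        fpr=MetricWithCI(fpr),
        operating_point=op,
        n=int(test_labels.size),
        prevalence=float(np.mean(test_labels)),
        stratum=stratum,
        extras={"apparent_auc": apparent_auc},
    )

    if per_rep:
        rep_auc, rep_mcr, rep_fnr, rep_fpr, rep_corr = [], [], [], [], []
        apparent_pool = dict(enumerate(per_rep_apparent)) if per_rep_apparent else {}
        for i, (p, y) in enumerate(per_rep):
            y = np.asarray(y, dtype=int)
            if len(np.unique(y)) < 2:
                continue
            a = pooled_auc(p, y)
            rep_auc.append(a)
            m, fn_, fp_ = transfer_operating_point(op.threshold, p, y)
            rep_mcr.append(m)
            rep_fnr.append(fn_)
            rep_fpr.append(fp_)
            if i in apparent_pool:
                ap, ay = apparent_pool[i]
                ay = np.asarray(ay, dtype=int)
                if len(np.unique(ay)) == 2:
                    rep_corr.append(auc_632plus(pooled_auc(ap, ay), a))
        for name, vals in (
            ("auc", rep_auc),
            ("mcr", rep_mcr),
            ("fnr", rep_fnr),
            ("fpr", rep_fpr),
            ("auc_632plus", rep_corr),
        ):
            if len(vals) >= 2:
                lo, hi = percentile_ci(vals, ci_level)
                m: MetricWithCI = getattr(metrics, name)
                m.ci_low, m.ci_high = lo, hi
    return metrics
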