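"""Cross-repetition aggregation of random-forest feature importances.

Per repetition the raw impurity-decrease scores are min-max normalized
to [0, 1]; features removed by that repetition's inter-feature filter
score 0; the per-feature averages over repetitions are then min-max
renormalized.  Features excluded before modelling (volume filter) never
appear in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ExperimentResult

logger = logging.getLogger(__name__)

HIGHLY_IMPORTANT_CUTOFF = 0.75


@dataclass
class ImportanceReport:
    feature_names: list[str]
    scores: np.ndarray  # aggregated, in [0, 1]
    per_rep_scores: np.ndarray  # (n_reps, n_features), normalized per rep

    def to_frame(self) -> pd.DataFrame:
        return (
            pd.DataFrame({"feature": self.feature_names, "score": self.scores})
            .sort_values("score", ascending=False)
            .reset_index(drop=True)
        )


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def aggregate_importance(
    raw_importances: list[np.ndarray],
    removed_masks: list[np.ndarray],
    feature_names: list[str],
) -> ImportanceReport:
    """Four-step aggregation: normalize, zero removed, average, renormalize.

    ``raw_importances[i]`` holds the forest's scores for the features kept
    by repetition ``i``; ``removed_masks[i]`` is the boolean inter-feature
    removal mask over the full ``feature_names`` ordering.
    """
    p = len(feature_names)
    n = len(raw_importances)
    per_rep = np.zeros((n, p))
    for i, (raw, mask) in enumerate(zip(raw_importances, removed_masks)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (p,):
            raise ValueError(f"repetition {i}: mask length {mask.shape} != {p}")
        kept = ~mask
        raw = np.asarray(raw, dtype=float)
        if raw.size != int(kept.sum()):
            raise ValueError(
                f"repetition {i}: {raw.size} scores for {int(kept.sum())} kept features"
            )
        if raw.size and raw.max() > 0:
            per_rep[i, kept] = _minmax(raw)
        else:
            logger.warning("repetition %d has all-zero importances", i)
        # removed features stay at 0
    mean = per_rep.mean(axis=0)
    return ImportanceReport(
        feature_names=list(feature_names),
        scores=_minmax(mean) if np.any(mean > 0) else mean,
        per_rep_scores=per_rep,
    )


def aggregate_experiment_importance(exp: ExperimentResult) -> ImportanceReport:
    """Convenience wrapper mapping an experiment's repetitions onto its features."""
    names = exp.feature_names
    raws = [r.importances for r in exp.repetitions]
    masks = [np.asarray(r.interfeature_removed, dtype=bool) for r in exp.repetitions]
    return aggregate_importance(raws, masks, names)


def highly_important(
    report: ImportanceReport, cutoff: float = HIGHLY_IMPORTANT_CUTOFF
) -> list[str]:
    """Features with aggregated score strictly above the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    return [
        f for f, s in zip(report.feature_names, report.scores) if s > cutoff
    ]


def plot_importance(report: ImportanceReport, path, top: int = 30) -> None:
    """Horizontal bar plot of the top aggregated scores (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.to_frame().head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(frame))))
    ax.barh(frame["feature"], frame["score"], color="#4878a8")
    ax.axvline(HIGHLY_IMPORTANT_CUTOFF, color="crimson", ls="--", lw=1)
    ax.set_xlabel("aggregated importance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
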