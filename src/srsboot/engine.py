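"""Patient-level bootstrap experiment engine.

Each repetition draws a bootstrap sample of *patients* (all lesions of a
patient travel together, so no patient contributes to both partitions),
applies the inter-feature correlation filter on training data only, fits
a random decision forest, and records test-set, out-of-bag and
resubstitution probabilities plus raw feature importances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .cohort import Cohort, design_matrix
from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

FEATURE_SETS = ("clinical", "radiomic", "both")


@dataclass
class EngineConfig:
    n_reps: int = 250
    n_trees: int = 500
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 1
    # Optional grid searched by out-of-bag AUC on the training data only;
    # None fits a single forest with the settings above.
    hyper_grid: list[dict] | None = None
    interfeature_cutoff: float = 0.95
    class_weight: str | None = None  # "balanced" switchable; default unweighted
    max_redraws: int = 50


def default_hyper_grid() -> list[dict]:
    """Standard grid: max features per split in {sqrt(p), p/3}, leaf size 1/3/5."""
    return [
        {"max_features": mf, "min_samples_leaf": leaf}
        for mf in ("sqrt", 0.333)
        for leaf in (1, 3, 5)
    ]


@dataclass
class RepetitionResult:
    rep: int
    seed: int
    train_patients: list[str]  # multiset, with multiplicity
    test_patients: list[str]
    test_bm_ids: list[str]
    test_probs: np.ndarray
    test_labels: np.ndarray
    train_bm_ids: list[str]  # unique training lesions
    oob_probs: np.ndarray  # NaN marks lesions never out of bag
    apparent_probs: np.ndarray
    train_labels: np.ndarray
    importances: np.ndarray
    interfeature_removed: np.ndarray  # bool mask over active_features
    active_features: list[str]
    hyperparams: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    repetitions: list[RepetitionResult]
    feature_set: str
    feature_names: list[str]
    seed: int
    removed_features: list[str] = field(default_factory=list)

    def pooled(self, partition: str) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (probabilities, labels) across repetitions."""
        probs, labels = [], []
        for r in self.repetitions:
            p, y = _partition_pairs(r, partition)
            probs.append(p)
            labels.append(y)
        return np.concatenate(probs), np.concatenate(labels)

    def per_rep(self, partition: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [_partition_pairs(r, partition) for r in self.repetitions]

    def to_table(self) -> pd.DataFrame:
        """Long probability table: rep, bm_id, partition, probability, label."""
        rows = []
        for r in self.repetitions:
            for bm, p, y in zip(r.test_bm_ids, r.test_probs, r.test_labels):
                rows.append((r.rep, bm, "test", p, y))
            for bm, p, q, y in zip(
                r.train_bm_ids, r.oob_probs, r.apparent_probs, r.train_labels
            ):
                if np.isfinite(p):
                    rows.append((r.rep, bm, "oob", p, y))
                rows.append((r.rep, bm, "apparent", q, y))
        return pd.DataFrame(
            rows, columns=["rep", "bm_id", "partition", "probability", "label"]
        )


def _partition_pairs(r: RepetitionResult, partition: str) -> tuple[np.ndarray, np.ndarray]:
    if partition == "test":
        return r.test_probs, r.test_labels
    if partition == "oob":
        ok = np.isfinite(r.oob_probs)
        return r.oob_probs[ok], r.train_labels[ok]
    if partition == "apparent":
        return r.apparent_probs, r.train_labels
    raise ValueError(f"unknown partition {partition!r}")


# ---------------------------------------------------------------------------
# Bootstrap draw


def draw_patient_bootstrap(
    patient_ids: Sequence[str],
    seed: int | np.random.Generator,
    max_redraws: int = 50,
) -> tuple[list[str], list[str]]:
    """Sample patients with replacement; never-drawn patients form the test set.

    Returns (training multiset, testing set).  The rare draw that selects
    every patient (empty test set) is redrawn from the next substream.
    """
    unique = list(dict.fromkeys(patient_ids))
    if len(unique) < 2:
        raise InsufficientDataError("need at least 2 patients to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for attempt in range(max_redraws):
        train = list(rng.choice(unique, size=len(unique), replace=True))
        test = [p for p in unique if p not in set(train)]
        if test:
            return train, test
        logger.warning("bootstrap draw %d left an empty test set; redrawing", attempt)
    raise InsufficientDataError("could not draw a non-empty test set")


# ---------------------------------------------------------------------------
# Inter-feature correlation filter


def filter_interfeature_correlation(
    X: pd.DataFrame,
    cutoff: float = 0.95,
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy removal mask so no retained pair has |Pearson r| > cutoff.

    Features are visited in descending univariate AUC order when training
    labels ``y`` are given (column order otherwise); a feature is kept if
    its absolute correlation with every already-kept feature is within
    the cutoff.  Constant features are removed with a warning.  Returns a
    boolean mask aligned with ``X.columns`` (True = removed).
    """
    cols = list(X.columns)
    mat = X.to_numpy(dtype=float)
    n, p = mat.shape
    removed = np.zeros(p, dtype=bool)
    std = mat.std(axis=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"removing {int(constant.sum())} constant feature(s) in correlation filter",
            stacklevel=2,
        )
        removed |= constant

    if y is not None and len(np.unique(y)) == 2:
        priority = np.array(
            [
                abs(roc_auc_score(y, mat[:, j]) - 0.5) if not constant[j] else -1.0
                for j in range(p)
            ]
        )
        order = np.argsort(-priority, kind="stable")
    else:
        order = np.arange(p)

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    kept: list[int] = []
    for j in order:
        if removed[j]:
            continue
        if any(abs(corr[j, k]) > cutoff for k in kept):
            removed[j] = True
        else:
            kept.append(j)
    return removed


# ---------------------------------------------------------------------------
# Model fitting


def _oob_positive_probs(forest: RandomForestClassifier) -> np.ndarray:
    """P(positive) per training row from out-of-bag trees only; NaN if none."""
    dec = forest.oob_decision_function_
    pos_col = int(np.flatnonzero(forest.classes_ == 1)[0])
    probs = dec[:, pos_col]
    # Rows never out of bag have all-NaN (sklearn >= 1.3) or all-zero rows.
    empty = ~np.isfinite(dec).all(axis=1) | (dec.sum(axis=1) == 0)
    probs = probs.copy()
    probs[empty] = np.nan
    return probs


def _fit_forest(
    X: np.ndarray, y: np.ndarray, cfg: EngineConfig, params: dict, seed: int
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=params.get("max_features", cfg.max_features),
        min_samples_leaf=params.get("min_samples_leaf", cfg.min_samples_leaf),
        oob_score=True,
        bootstrap=True,
        class_weight=cfg.class_weight,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", message="invalid value encountered")
        forest.fit(X, y)
    return forest


def fit_and_predict(
    rep: int,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    train_bm_ids: Sequence[str],
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    test_bm_ids: Sequence[str],
    config: EngineConfig,
    seed: int,
    train_patients: Sequence[str] = (),
    test_patients: Sequence[str] = (),
) -> RepetitionResult:
    """Filter, fit and score one repetition.

    Raises :class:`InsufficientDataError` when training data has a single
    class (callers redraw the partition).
    """
    y_train = np.asarray(y_train, dtype=int)
    y_test = np.asarray(y_test, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise InsufficientDataError(f"repetition {rep}: single-class training data")

    mask = filter_interfeature_correlation(
        X_train, cutoff=config.interfeature_cutoff, y=y_train
    )
    active = [c for c, m in zip(X_train.columns, mask) if not m]
    Xtr = X_train[active].to_numpy(dtype=float)
    Xte = X_test[active].to_numpy(dtype=float)

    grid = config.hyper_grid if config.hyper_grid else [{}]
    best, best_params, best_score = None, {}, -np.inf
    for params in grid:
        forest = _fit_forest(Xtr, y_train, config, params, seed)
        if len(grid) == 1:
            best, best_params = forest, params
            break
        oob = _oob_positive_probs(forest)
        ok = np.isfinite(oob)
        score = (
            roc_auc_score(y_train[ok], oob[ok])
            if len(np.unique(y_train[ok])) == 2
            else -np.inf
        )
        if score > best_score:
            best, best_params, best_score = forest, params, score
    assert best is not None

    pos_col = int(np.flatnonzero(best.classes_ == 1)[0])
    result = RepetitionResult(
        rep=rep,
        seed=seed,
        train_patients=list(train_patients),
        test_patients=list(test_patients),
        test_bm_ids=list(test_bm_ids),
        test_probs=best.predict_proba(Xte)[:, pos_col],
        test_labels=y_test,
        train_bm_ids=list(train_bm_ids),
        oob_probs=_oob_positive_probs(best),
        apparent_probs=best.predict_proba(Xtr)[:, pos_col],
        train_labels=y_train,
        importances=best.feature_importances_.copy(),
        interfeature_removed=mask,
        active_features=active,
        hyperparams=dict(best_params),
    )
    return result


# ---------------------------------------------------------------------------
# Experiment loop


def run_experiment(
    cohort: Cohort,
    feature_set: str = "both",
    n_reps: int | None = None,
    removed_features: Iterable[str] = (),
    seed: int = 0,
    config: EngineConfig | None = None,
) -> ExperimentResult:
    """Run the full bootstrapped experiment on one cohort.

    ``removed_features`` (typically from the volume filter) are dropped
    before feature-set selection.  Per-repetition seeds are substreams of
    the global seed, and partition draws depend only on the substream and
    the patient list — arms sharing a seed share partitions.
    """
    config = config or EngineConfig()
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    n_reps = n_reps if n_reps is not None else config.n_reps

    X = design_matrix(cohort, feature_set, removed=removed_features)
    y = cohort.labels
    df = cohort.df
    patients = list(dict.fromkeys(df["patient_id"]))
    by_patient = {p: np.flatnonzero(df["patient_id"].to_numpy() == p) for p in patients}

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    reps: list[RepetitionResult] = []
    for i, child in enumerate(children):
        part_rng = np.random.default_rng(child)
        fit_seed = int(np.random.default_rng(child.spawn(1)[0]).integers(2**31))
        for attempt in range(config.max_redraws):
            train_pat, test_pat = draw_patient_bootstrap(patients, part_rng)
            tr_idx = np.concatenate([by_patient[p] for p in train_pat])
            te_idx = np.concatenate([by_patient[p] for p in test_pat])
            if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[te_idx])) < 1:
                logger.warning("rep %d draw %d single-class; redrawing", i, attempt)
                continue
            break
        else:
            raise InsufficientDataError(f"repetition {i}: no usable partition found")

        reps.append(
            fit_and_predict(
                rep=i,
                X_train=X.iloc[tr_idx],
                y_train=y[tr_idx],
                train_bm_ids=list(df["bm_id"].to_numpy()[tr_idx]),
                X_test=X.iloc[te_idx],
                y_test=y[te_idx],
                test_bm_ids=list(df["bm_id"].to_numpy()[te_idx]),
                config=config,
                seed=fit_seed,
                train_patients=train_pat,
                test_patients=test_pat,
            )
        )
    return ExperimentResult(
        repetitions=reps,
        feature_set=feature_set,
        feature_names=list(X.columns),
        seed=seed,
        removed_features=list(removed_features),
    )
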