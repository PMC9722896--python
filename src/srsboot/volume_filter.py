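"""Volume-decorrelation feature removal and univariate association tests.

Categorical features are tested for dependence on lesion volume with the
rank-sum test (binary) or Kruskal-Wallis test (multi-level); continuous
features get Pearson correlations against both volume and its cubic root
(a diameter analogue).  Significance is Bonferroni-controlled at
``0.05 / 118`` by default, and a continuous feature is removed only when
the larger absolute coefficient also exceeds the chosen threshold.  A
threshold of 1 is the baseline that removes nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    BINARY_CLINICAL,
    CLINICAL_COLUMNS,
    CONTINUOUS_CLINICAL,
    Cohort,
)
from .errors import DegenerateInputError, UndefinedMetricError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05 / 118
SWEEP_THRESHOLDS = (1.0, 0.85, 0.70, 0.55, 0.40, 0.25, 0.10, 0.0)


@dataclass
class FilterDecision:
    feature: str
    feature_class: str  # "categorical" | "continuous"
    test: str
    p_value: float
    r_volume: float = float("nan")
    r_diameter: float = float("nan")
    p_volume: float = float("nan")
    p_diameter: float = float("nan")
    removed: bool = False
    threshold: float = float("nan")


@dataclass
class SweepResult:
    thresholds: list[float]
    removal_sets: dict[float, set[str]]
    metrics: dict[float, dict[str, object]]  # threshold -> stratum -> ErrorMetrics
    decisions: dict[float, list[FilterDecision]] = field(default_factory=dict)


def _ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when samples are small and tie-free, otherwise the normal
    approximation with tie correction.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) < 50 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def test_categorical_volume_dependence(values, volumes) -> float:
    """Rank-sum p for binary features, Kruskal-Wallis otherwise."""
    values = np.asarray(values)
    volumes = np.asarray(volumes, dtype=float)
    groups = []
    for cat in pd.unique(values):
        vols = volumes[values == cat]
        if vols.size < 1:
            warnings.warn(f"dropping empty category {cat!r}", stacklevel=2)
            continue
        groups.append(vols)
    if len(groups) < 2:
        raise UndefinedMetricError("fewer than 2 non-empty categories; test skipped")
    if len(groups) == 2:
        return _ranksum(groups[0], groups[1])
    return float(stats.kruskal(*groups).pvalue)


def test_continuous_volume_correlation(
    values, volumes
) -> tuple[float, float, float, float]:
    """(r_vol, p_vol, r_diam, p_diam): Pearson vs volume and its cubic root."""
    x = np.asarray(values, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    if np.std(x) == 0 or np.std(v) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    r_vol, p_vol = stats.pearsonr(x, v)
    r_diam, p_diam = stats.pearsonr(x, np.cbrt(v))
    return float(r_vol), float(p_vol), float(r_diam), float(p_diam)


def select_features_for_removal(
    cohort: Cohort,
    threshold: float = 0.25,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[set[str], list[FilterDecision]]:
    """Apply the volume-decorrelation rule to every clinical and radiomic feature.

    Categorical clinical features are removed iff their volume-dependence
    p-value is below ``alpha``.  Continuous features (radiomic plus age
    and the volume itself) are removed iff either correlation p-value is
    significant AND ``max(|r_vol|, |r_diam|)`` exceeds ``threshold``.  At
    threshold 1 nothing is removed (baseline).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    decisions: list[FilterDecision] = []
    removed: set[str] = set()
    if threshold >= 1.0:
        return removed, decisions

    volumes = cohort.volumes
    for col in CLINICAL_COLUMNS:
        if col == "gtv_volume" or col in CONTINUOUS_CLINICAL:
            continue
        binary = col in BINARY_CLINICAL or cohort.df[col].nunique() == 2
        try:
            p = test_categorical_volume_dependence(cohort.df[col].to_numpy(), volumes)
        except UndefinedMetricError:
            continue
        d = FilterDecision(
            feature=col,
            feature_class="categorical",
            test="ranksum" if binary else "kruskal",
            p_value=p,
            removed=p < alpha,
            threshold=threshold,
        )
        decisions.append(d)
        if d.removed:
            removed.add(col)

    continuous = [
        c for c in CONTINUOUS_CLINICAL if c != "gtv_volume"
    ] + cohort.radiomic_cols
    for col in continuous:
        try:
            r_vol, p_vol, r_diam, p_diam = test_continuous_volume_correlation(
                cohort.df[col].to_numpy(dtype=float), volumes
            )
        except DegenerateInputError:
            logger.warning("feature %s constant; correlation test skipped", col)
            continue
        significant = (p_vol < alpha) or (p_diam < alpha)
        magnitude = max(abs(r_vol), abs(r_diam))
        d = FilterDecision(
            feature=col,
            feature_class="continuous",
            test="pearson",
            p_value=min(p_vol, p_diam),
            r_volume=r_vol,
            r_diameter=r_diam,
            p_volume=p_vol,
            p_diameter=p_diam,
            removed=bool(significant and magnitude > threshold),
            threshold=threshold,
        )
        decisions.append(d)
        if d.removed:
            removed.add(col)

    # Volume itself is a perfect self-correlate: always removed below 1.
    removed.add("gtv_volume")
    decisions.append(
        FilterDecision(
            feature="gtv_volume",
            feature_class="continuous",
            test="identity",
            p_value=0.0,
            r_volume=1.0,
            r_diameter=float(
                stats.pearsonr(volumes, np.cbrt(volumes))[0]
            ),
            removed=True,
            threshold=threshold,
        )
    )
    return removed, decisions


def decisions_frame(decisions: list[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in decisions])


def threshold_sweep(
    cohort: Cohort,
    thresholds=SWEEP_THRESHOLDS,
    engine_config=None,
    feature_set: str = "both",
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    n_reps: int | None = None,
) -> SweepResult:
    """Rerun the full experiment at each threshold; metrics per volume group."""
    # Imported here: stratify depends on engine which is independent of us.
    from .engine import run_experiment
    from .stratify import stratified_metrics, volume_groups

    removal_sets: dict[float, set[str]] = {}
    metrics: dict[float, dict[str, object]] = {}
    all_decisions: dict[float, list[FilterDecision]] = {}
    for t in thresholds:
        removed, dec = select_features_for_removal(cohort, threshold=t, alpha=alpha)
        removal_sets[t] = removed
        all_decisions[t] = dec
        exp = run_experiment(
            cohort,
            feature_set=feature_set,
            n_reps=n_reps,
            removed_features=removed,
            seed=seed,
            config=engine_config,
        )
        metrics[t] = stratified_metrics(exp, volume_groups(cohort), cohort=cohort)
    return SweepResult(
        thresholds=list(thresholds),
        removal_sets=removal_sets,
        metrics=metrics,
        decisions=all_decisions,
    )


def site_dependence_filter(
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
    min_site_count: int = 3,
) -> set[str]:
    """Remove features dependent on primary site (plus the site itself).

    Continuous features are tested with Kruskal-Wallis across sites,
    categorical clinical features with a chi-squared contingency test.
    Sites below ``min_site_count`` lesions are pooled into "other".
    """
    sites = cohort.df["primary_site"].astype(str).copy()
    counts = sites.value_counts()
    sparse = counts[counts < min_site_count].index
    if len(sparse):
        logger.warning("pooling sparse sites into 'other': %s", list(sparse))
        sites[sites.isin(sparse)] = "other"
    if sites.nunique() < 2:
        raise UndefinedMetricError("fewer than 2 primary sites present")

    removed: set[str] = {"primary_site"}
    site_arr = sites.to_numpy()
    for col in cohort.radiomic_cols + CONTINUOUS_CLINICAL:
        x = cohort.df[col].to_numpy(dtype=float)
        groups = [x[site_arr == s] for s in np.unique(site_arr)]
        if any(np.std(g) == 0 and g.size > 1 for g in groups) and np.std(x) == 0:
            continue
        p = float(stats.kruskal(*groups).pvalue)
        if p < alpha:
            removed.add(col)
    for col in CLINICAL_COLUMNS:
        if col in CONTINUOUS_CLINICAL or col == "primary_site":
            continue
        table = pd.crosstab(cohort.df[col], sites)
        if table.shape[0] < 2:
            continue
        _, p = chi_squared_test(table.to_numpy())
        if p < alpha:
            removed.add(col)
    return removed


def chi_squared_test(table) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a contingency table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("contingency table must be 2-D with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateInputError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def univariate_association_tests(cohort: Cohort) -> pd.DataFrame:
    """Per-feature association with the progression label.

    Chi-squared for categorical clinical features, two-sided rank-sum
    for the continuous ones (age, volume); constant features are skipped
    with a warning.
    """
    y = cohort.labels
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("both outcome classes required")
    rows = []
    for col in CLINICAL_COLUMNS:
        vals = cohort.df[col]
        if col in CONTINUOUS_CLINICAL:
            x = vals.to_numpy(dtype=float)
            if np.std(x) == 0:
                warnings.warn(f"constant feature {col!r}; test skipped", stacklevel=2)
                continue
            p = _ranksum(x[y == 1], x[y == 0])
            rows.append({"feature": col, "test": "ranksum", "p_value": p})
        else:
            if vals.nunique() < 2:
                warnings.warn(f"constant feature {col!r}; test skipped", stacklevel=2)
                continue
            table = pd.crosstab(y, vals).to_numpy()
            _, p = chi_squared_test(table)
            rows.append({"feature": col, "test": "chi_squared", "p_value": p})
    return pd.DataFrame(rows)
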