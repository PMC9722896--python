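"""Synthetic per-lesion cohorts with a configurable statistical structure.

Generates patients bearing 1-3 brain metastases each, with categorical
clinical features drawn from configurable frequencies, log-normal lesion
volumes, radiomic-like continuous features built from a latent signal
plus a volume-coupled term plus scanner shift plus noise, and a logistic
outcome model.  Everything is driven by a single seed so cohorts are
byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# Schema

N_RADIOMIC_DEFAULT = 107

CLINICAL_COLUMNS = [
    "sex",
    "age",
    "primary_active",
    "primary_site",
    "histology",
    "extracranial_mets",
    "systemic_therapy",
    "steroid_response",
    "ecog_who",
    "gtv_volume",
    "bm_location",
    "srs_prescription",
]

CONTINUOUS_CLINICAL = ["age", "gtv_volume"]
BINARY_CLINICAL = ["sex", "primary_active", "extracranial_mets", "bm_location"]

PRESCRIPTION_LEVELS = [
    "15Gy/1fx",
    "18Gy/1fx",
    "21Gy/1fx",
    "24Gy/3fx",
]

DEFAULT_CLINICAL_FREQS: dict[str, dict[str, float]] = {
    "sex": {"female": 66 / 123, "male": 57 / 123},
    "primary_active": {"yes": 55 / 123, "no": 68 / 123},
    "primary_site": {
        "lung": 70 / 123,
        "breast": 14 / 123,
        "renal": 15 / 123,
        "colorectal": 10 / 123,
        "skin": 9 / 123,
        "other": 5 / 123,
    },
    "histology": {
        "adenocarcinoma": 65 / 123,
        "nsclc": 36 / 123,
        "melanoma": 9 / 123,
        "squamous": 8 / 123,
        "other": 5 / 123,
    },
    "extracranial_mets": {"yes": 50 / 123, "no": 73 / 123},
    "systemic_therapy": {"radical": 10 / 123, "palliative": 60 / 123, "none": 53 / 123},
    "steroid_response": {
        "fully_resolved": 31 / 123,
        "improvement": 4 / 123,
        "limited": 56 / 123,
        "none": 11 / 123,
        "unknown": 21 / 123,
    },
    "ecog_who": {"0": 39 / 123, "1": 73 / 123, "2": 9 / 123, "3": 2 / 123},
    "bm_location": {"supratentorial": 96 / 123, "infratentorial": 27 / 123},
}

PATIENT_LEVEL_FEATURES = [
    "sex",
    "primary_active",
    "primary_site",
    "histology",
    "extracranial_mets",
    "systemic_therapy",
    "steroid_response",
    "ecog_who",
]


class ScannerConfig(NamedTuple):
    model: str
    orientation: str
    voxel_size: str
    prob: float


DEFAULT_SCANNERS: list[ScannerConfig] = [
    ScannerConfig("Vision", "sagittal", "1x1x1.5", 39 / 123),
    ScannerConfig("Avanto", "sagittal", "0.5x0.5x1", 37 / 123),
    ScannerConfig("Avanto", "axial", "0.5x0.5x2", 8 / 123),
    ScannerConfig("Expert", "sagittal", "1x1x1.5", 29 / 123),
    ScannerConfig("Sonata", "sagittal", "1x1x1.5", 5 / 123),
    ScannerConfig("Sonata", "axial", "1x1x1.5", 1 / 123),
    ScannerConfig("Sonata", "axial", "1x1x2", 3 / 123),
    ScannerConfig("SignaHDxt", "sagittal", "1x1x1.5", 1 / 123),
]

MAJOR_SCANNER_MODELS = ("Vision", "Avanto", "Expert")


def scanner_model(tag: str) -> str:
    """Model name from a 'model|orientation|voxel' scanner tag."""
    return tag.split("|", 1)[0]


def radiomic_columns(n: int = N_RADIOMIC_DEFAULT) -> list[str]:
    return [f"f{i + 1:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class OutcomeModel:
    """Logistic outcome model on latent signal channels and log-volume."""

    intercept: float = -2.12
    volume_coef: float = 0.9
    signal_weights: tuple[float, ...] = (1.1, 1.1, 0.9, 0.9)
    site_attenuation: dict[str, float] = field(default_factory=dict)

    def attenuation(self, site: str) -> float:
        return self.site_attenuation.get(site, 1.0)


@dataclass
class ScannerEffect:
    """Additive offset and variance scaling applied to radiomic features."""

    offset: float = 0.0
    scale: float = 1.0


@dataclass
class CohortConfig:
    n_patients: int = 99
    # P(1), P(2), P(3) lesions per patient; E = 1.24 -> ~123 lesions for 99.
    bm_count_probs: tuple[float, float, float] = (0.80, 0.16, 0.04)
    clinical_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_FREQS.items()}
    )
    volume_median_cc: float = 3.07
    volume_log_sigma: float = 1.25
    volume_clamp_cc: tuple[float, float] = (0.02, 30.23)
    age_mean: float = 59.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (38.0, 86.0)
    n_radiomic: int = N_RADIOMIC_DEFAULT
    volume_corr_targets: np.ndarray | None = None  # per-feature rho vs log-volume
    signal_loading: np.ndarray | None = None  # per-feature loading on a channel
    signal_channel: np.ndarray | None = None  # per-feature channel index
    n_signal_channels: int = 4
    volume_correlated_fraction: float = 0.74
    scanners: list[ScannerConfig] = field(default_factory=lambda: list(DEFAULT_SCANNERS))
    scanner_effects: dict[str, ScannerEffect] = field(default_factory=dict)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    censor_prob: float = 0.0
    dose_rule_violation_rate: float = 0.05
    seed: int = 0

    # -- resolved per-feature arrays ------------------------------------
    def resolve_feature_structure(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (rho, loading, channel) arrays of length ``n_radiomic``.

        Default layout: the first ``volume_correlated_fraction`` of
        features get volume correlations spread over [0.30, 0.95] and no
        signal loading; of the remainder, the first eight carry the
        latent outcome signal.
        """
        p = self.n_radiomic
        if self.volume_corr_targets is not None:
            rho = np.asarray(self.volume_corr_targets, dtype=float)
        else:
            rho = np.zeros(p)
            n_corr = int(round(self.volume_correlated_fraction * p))
            if n_corr:
                rho[:n_corr] = np.linspace(0.30, 0.95, n_corr)
        if rho.shape != (p,):
            raise ConfigurationError(
                f"volume_corr_targets must have length {p}, got {rho.shape}"
            )
        if np.any(np.abs(rho) > 1.0):
            raise ConfigurationError("correlation targets must lie in [-1, 1]")

        if self.signal_loading is not None:
            loading = np.asarray(self.signal_loading, dtype=float)
        else:
            loading = np.zeros(p)
            free = np.flatnonzero(rho == 0.0)
            loading[free[:8]] = 0.85
        if loading.shape != (p,) or np.any((loading < 0) | (loading >= 1.0001)):
            raise ConfigurationError("signal loadings must lie in [0, 1]")
        loading = np.clip(loading, 0.0, 1.0)

        if self.signal_channel is not None:
            channel = np.asarray(self.signal_channel, dtype=int)
        else:
            channel = np.arange(p) % max(self.n_signal_channels, 1)
        if channel.shape != (p,):
            raise ConfigurationError("signal_channel must match n_radiomic")
        return rho, loading, channel

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not math.isclose(sum(self.bm_count_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("bm_count_probs must sum to 1")
        for name, freqs in self.clinical_freqs.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ConfigurationError(
                    f"frequencies for {name!r} sum to {total:.6f}, expected 1"
                )
            if any(v < 0 for v in freqs.values()):
                raise ConfigurationError(f"negative frequency in {name!r}")
        total = sum(s.prob for s in self.scanners)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigurationError(f"scanner probabilities sum to {total:.6f}")
        if self.volume_clamp_cc[0] <= 0:
            raise ConfigurationError("volume clamp must be positive")
        self.resolve_feature_structure()

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("volume_corr_targets", "signal_loading", "signal_channel"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        d["scanners"] = [list(s) for s in self.scanners]
        return d


# ---------------------------------------------------------------------------
# Cohort container


@dataclass
class Cohort:
    """A feature table (one row per lesion) plus generation side-products."""

    df: pd.DataFrame
    latents: np.ndarray | None = None  # (n_bm, n_channels) latent signal draws
    log_volume_z: np.ndarray | None = None
    config: CohortConfig | None = None

    @property
    def n_bms(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def volumes(self) -> np.ndarray:
        return self.df["gtv_volume"].to_numpy(dtype=float)

    @property
    def radiomic_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("f") and c[1:].isdigit()]

    def radiomic_frame(self) -> pd.DataFrame:
        return self.df[self.radiomic_cols]

    def clinical_frame(self) -> pd.DataFrame:
        return self.df[CLINICAL_COLUMNS]

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(
            df=self.df.loc[mask].reset_index(drop=True),
            latents=self.latents[np.asarray(mask)] if self.latents is not None else None,
            log_volume_z=(
                self.log_volume_z[np.asarray(mask)]
                if self.log_volume_z is not None
                else None
            ),
            config=self.config,
        )


# ---------------------------------------------------------------------------
# Generation


def _draw_categorical(rng: np.random.Generator, freqs: dict[str, float], n: int) -> np.ndarray:
    cats = list(freqs.keys())
    probs = np.array([freqs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(cats, size=n, p=probs)


def _assign_prescription(
    rng: np.random.Generator, volumes: np.ndarray, violation_rate: float
) -> np.ndarray:
    """7.5 cc rule: small lesions get the most aggressive prescription."""
    small_menu = (["21Gy/1fx", "18Gy/1fx"], [0.77, 0.23])
    large_menu = (["18Gy/1fx", "15Gy/1fx", "24Gy/3fx"], [0.45, 0.17, 0.38])
    out = np.empty(volumes.size, dtype=object)
    for i, v in enumerate(volumes):
        small = v < 7.5
        if rng.random() < violation_rate:
            small = not small
        menu, probs = small_menu if small else large_menu
        out[i] = rng.choice(menu, p=probs)
    return out


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a synthetic cohort; deterministic given ``config.seed``."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    rho, loading, channel = config.resolve_feature_structure()

    n_pat = config.n_patients
    bm_counts = rng.choice([1, 2, 3], size=n_pat, p=np.asarray(config.bm_count_probs))
    n_bm = int(bm_counts.sum())

    patient_rows: dict[str, np.ndarray] = {}
    for feat in PATIENT_LEVEL_FEATURES:
        patient_rows[feat] = _draw_categorical(rng, config.clinical_freqs[feat], n_pat)
    ages = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n_pat), *config.age_range
    ).round(1)

    scanner_tags = np.array(
        ["|".join(s[:3]) for s in config.scanners], dtype=object
    )
    scanner_probs = np.array([s.prob for s in config.scanners], dtype=float)
    scanner_probs = scanner_probs / scanner_probs.sum()
    patient_scanner = rng.choice(scanner_tags, size=n_pat, p=scanner_probs)

    # Expand to one row per lesion.
    rep = np.repeat(np.arange(n_pat), bm_counts)
    patient_id = np.array([f"P{i + 1:03d}" for i in range(n_pat)], dtype=object)[rep]
    within = np.concatenate([np.arange(c) for c in bm_counts])
    bm_id = np.array(
        [f"{p}-BM{j + 1}" for p, j in zip(patient_id, within)], dtype=object
    )

    log_med = math.log(config.volume_median_cc)
    log_vol = rng.normal(log_med, config.volume_log_sigma, size=n_bm)
    volumes = np.clip(np.exp(log_vol), *config.volume_clamp_cc)
    log_vol = np.log(volumes)
    sd = log_vol.std()
    z = (log_vol - log_vol.mean()) / (sd if sd > 0 else 1.0)

    location = _draw_categorical(rng, config.clinical_freqs["bm_location"], n_bm)
    prescription = _assign_prescription(rng, volumes, config.dose_rule_violation_rate)

    # Radiomic features: volume-coupled + latent-signal + noise, then
    # per-scanner affine shift.
    n_channels = max(config.n_signal_channels, 1)
    latents = rng.normal(size=(n_bm, n_channels))
    noise = rng.normal(size=(n_bm, config.n_radiomic))
    sig = latents[:, channel] * loading + noise * np.sqrt(1.0 - loading**2)
    feats = rho * z[:, None] + np.sqrt(1.0 - rho**2) * sig

    bm_scanner = patient_scanner[rep]
    for tag in np.unique(bm_scanner):
        eff = config.scanner_effects.get(scanner_model(tag))
        if eff is None:
            eff = config.scanner_effects.get(tag)
        if eff is None:
            continue
        rows = bm_scanner == tag
        feats[rows] = feats[rows] * eff.scale + eff.offset

    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "bm_id": bm_id,
            "sex": patient_rows["sex"][rep],
            "age": ages[rep],
            "primary_active": patient_rows["primary_active"][rep],
            "primary_site": patient_rows["primary_site"][rep],
            "histology": patient_rows["histology"][rep],
            "extracranial_mets": patient_rows["extracranial_mets"][rep],
            "systemic_therapy": patient_rows["systemic_therapy"][rep],
            "steroid_response": patient_rows["steroid_response"][rep],
            "ecog_who": patient_rows["ecog_who"][rep],
            "gtv_volume": volumes.round(4),
            "bm_location": location,
            "srs_prescription": prescription,
            "scanner": bm_scanner,
        }
    )
    rad = pd.DataFrame(
        feats.round(6), columns=radiomic_columns(config.n_radiomic), index=df.index
    )
    df = pd.concat([df, rad], axis=1)

    cohort = Cohort(df=df, latents=latents, log_volume_z=z, config=config)
    cohort.df["label"] = assign_outcomes(
        cohort, config.outcome, seed=int(rng.integers(2**31))
    )
    if config.censor_prob > 0:
        flip = rng.random(n_bm) < config.censor_prob
        cohort.df.loc[flip & (cohort.df["label"] == 1), "label"] = 0
    return cohort


def assign_outcomes(
    cohort: Cohort, model: OutcomeModel, seed: int | None = None
) -> np.ndarray:
    """Draw binary labels from the logistic outcome model.

    The linear predictor is ``intercept + volume_coef * z(log V) +
    attenuation(site) * sum_c w_c s_c`` with per-lesion independent
    Bernoulli draws; reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    eta = linear_predictor(cohort, model)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(p)) < p).astype(int)


def linear_predictor(cohort: Cohort, model: OutcomeModel) -> np.ndarray:
    """The generating score used by :func:`assign_outcomes`."""
    if cohort.latents is None or cohort.log_volume_z is None:
        raise ConfigurationError("cohort lacks latent generation side-products")
    w = np.asarray(model.signal_weights, dtype=float)
    n_ch = cohort.latents.shape[1]
    w = w[:n_ch] if w.size >= n_ch else np.pad(w, (0, n_ch - w.size))
    att = np.array(
        [model.attenuation(s) for s in cohort.df["primary_site"]], dtype=float
    )
    return (
        model.intercept
        + model.volume_coef * cohort.log_volume_z
        + att * (cohort.latents @ w)
    )


# ---------------------------------------------------------------------------
# Preset study designs for recovery experiments


def volume_confounded_config(seed: int = 5) -> CohortConfig:
    """Design for volume-blinding recovery experiments.

    The outcome depends on a latent signal carried partly by
    volume-contaminated features (rho 0.7, removed by the volume filter
    at threshold 0.25) and partly by clean views (retained), plus a
    moderate direct volume effect.  Removing the contaminated block
    strips the volume-noise component from the predictions, which hits
    the two volume groups asymmetrically.
    """
    p = N_RADIOMIC_DEFAULT
    rho = np.zeros(p)
    rho[:60] = 0.7
    loading = np.zeros(p)
    loading[:60] = 0.6
    loading[60:68] = 0.9
    return CohortConfig(
        seed=seed,
        volume_corr_targets=rho,
        signal_loading=loading,
        volume_median_cc=4.0,
        volume_log_sigma=1.3,
        outcome=OutcomeModel(
            intercept=-2.5, volume_coef=0.7, signal_weights=(1.5, 1.5, 1.5, 1.5)
        ),
    )


def scanner_shift_config(
    seed: int = 11, shifted_model: str = "Avanto"
) -> CohortConfig:
    """Design for scanner domain-shift recovery experiments.

    Three majority scanner models with one given a large planted affine
    covariate shift; the outcome signal is volume-independent and strong
    enough for pairings of unshifted scanners to recover it.
    """
    p = N_RADIOMIC_DEFAULT
    loading = np.zeros(p)
    loading[:24] = 0.9
    return CohortConfig(
        seed=seed,
        volume_corr_targets=np.zeros(p),
        signal_loading=loading,
        scanners=[
            ScannerConfig("Vision", "sagittal", "1x1x1.5", 0.4),
            ScannerConfig("Avanto", "sagittal", "0.5x0.5x1", 0.3),
            ScannerConfig("Expert", "sagittal", "1x1x1.5", 0.3),
        ],
        scanner_effects={shifted_model: ScannerEffect(offset=4.0, scale=3.0)},
        outcome=OutcomeModel(
            intercept=-1.9, volume_coef=0.3, signal_weights=(1.4, 1.4, 1.2, 1.2)
        ),
    )


# ---------------------------------------------------------------------------
# Progression scoring


class DiameterTriple(NamedTuple):
    """Maximum lesion diameters (mm) in three perpendicular directions."""

    si: float
    ml: float
    pa: float


def score_progression(pre: DiameterTriple, post: DiameterTriple) -> int:
    """1 iff the diameter product grew by >= 25% (inclusive boundary)."""
    for d in (*pre, *post):
        if not d > 0:
            raise ValueError(f"diameters must be positive, got {d}")
    ratio = (post.si * post.ml * post.pa) / (pre.si * pre.ml * pre.pa)
    return int(ratio >= 1.25)


# ---------------------------------------------------------------------------
# Delimited-text round trip


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """One row per lesion as TSV, plus a sidecar config echo in JSON."""
    path = Path(path)
    cohort.df.to_csv(path, sep="\t", index=False)
    if cohort.config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(json.dumps(cohort.config.to_jsonable(), indent=2))


def read_cohort(path: str | Path) -> Cohort:
    df = pd.read_csv(path, sep="\t")
    required = ["patient_id", "bm_id", "label", "scanner", *CLINICAL_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort table missing columns: {missing}")
    return Cohort(df=df)


# ---------------------------------------------------------------------------
# Model design matrix

_CATEGORY_ORDERS: dict[str, list[str]] = {
    **{k: list(v.keys()) for k, v in DEFAULT_CLINICAL_FREQS.items()},
    "srs_prescription": PRESCRIPTION_LEVELS,
}


def design_matrix(
    cohort: Cohort,
    feature_set: str = "both",
    removed: Iterable[str] = (),
) -> pd.DataFrame:
    """Numeric model matrix for the requested feature set.

    Categorical clinical features are encoded as stable integer codes
    (tree models split on them directly); continuous features pass
    through.  ``removed`` columns are dropped after encoding.
    """
    if feature_set not in ("clinical", "radiomic", "both"):
        raise ConfigurationError(f"unknown feature set {feature_set!r}")
    removed = set(removed)
    cols: dict[str, np.ndarray] = {}
    if feature_set in ("clinical", "both"):
        for c in CLINICAL_COLUMNS:
            if c in removed:
                continue
            if c in CONTINUOUS_CLINICAL:
                cols[c] = cohort.df[c].to_numpy(dtype=float)
            else:
                order = _CATEGORY_ORDERS.get(c)
                vals = cohort.df[c].astype(str)
                if order:
                    mapping = {cat: i for i, cat in enumerate(order)}
                    codes = vals.map(mapping)
                    if codes.isna().any():
                        codes = pd.Categorical(vals).codes
                else:
                    codes = pd.Categorical(vals).codes
                cols[c] = np.asarray(codes, dtype=float)
    if feature_set in ("radiomic", "both"):
        for c in cohort.radiomic_cols:
            if c in removed:
                continue
            cols[c] = cohort.df[c].to_numpy(dtype=float)
    out = pd.DataFrame(cols, index=cohort.df.index)
    if out.empty:
        raise ConfigurationError("no features left after removal")
    return out
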