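"""Synthetic screening cohorts with class-conditional bivariate-normal AI scores.

The generator emulates a breast-screening case collection in which every case
carries a ground-truth class (``malignant`` / ``benign`` / ``normal``), one
continuous suspicion score per imaging modality (digital mammography, ``dm``,
and automated 3D breast ultrasound, ``abus``), and optionally ordinal BI-RADS
assessments from simulated readers.

The generative family is the binormal ROC model: within each truth class the
(dm, abus) score pair is drawn from a bivariate Gaussian with a per-class
inter-modality correlation ``rho``.  The binormal family admits a closed-form
AUC, :func:`analytic_auc`, which downstream tests use as an exact oracle.

Benign and normal cases have separate score distributions (benign lesions are
typically scored above normal tissue by detection systems); they are pooled
into the negative class only when binary labels are formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CLASSES",
    "MODALITIES",
    "BIRADS_CATEGORIES",
    "CATEGORY_RANK",
    "CASE_TABLE_COLUMNS",
    "CohortConfig",
    "ClassScoreModel",
    "BinormalModelSpec",
    "ReaderProfile",
    "DEFAULT_MODEL",
    "DEFAULT_READER_PROFILES",
    "DEFAULT_READER_NAMES",
    "generate_cohort",
    "analytic_auc",
    "generate_reader_scores",
    "profile_from_operating_point",
    "observer_subcohort",
    "validate_case_table",
]

#: Ground-truth vocabulary, ordered by decreasing clinical severity.
CLASSES = ("malignant", "benign", "normal")

#: The two imaging modalities whose AI scores are fused downstream.
MODALITIES = ("dm", "abus")

#: BI-RADS assessment categories in increasing order of suspicion
#: (1 = negative, 2 = benign, 3 = probably benign, 4a/4b/4c = suspicious,
#: 5 = highly suggestive of malignancy).
BIRADS_CATEGORIES = ("1", "2", "3", "4a", "4b", "4c", "5")

#: Suspicion rank of each category (1 < 2 < 3 < 4a < 4b < 4c < 5).
CATEGORY_RANK = {c: i for i, c in enumerate(BIRADS_CATEGORIES)}

#: Mandatory case-table columns; any further column is an ordinal reader column.
CASE_TABLE_COLUMNS = ("case_id", "truth_class", "score_dm", "score_abus")


class ConfigurationError(ValueError):
    """Raised when a cohort/model/profile specification is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Class composition and seed of a synthetic cohort.

    Defaults reproduce a 430-case screening collection enriched with biopsy
    cases: 42 malignant, 114 benign, 274 normal.
    """

    n_malignant: int = 42
    n_benign: int = 114
    n_normal: int = 274
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_malignant", "n_benign", "n_normal"):
            n = getattr(self, name)
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {n!r}")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "malignant": self.n_malignant,
            "benign": self.n_benign,
            "normal": self.n_normal,
        }

    @property
    def n_total(self) -> int:
        return self.n_malignant + self.n_benign + self.n_normal


@dataclass(frozen=True)
class ClassScoreModel:
    """Bivariate-Gaussian score model for one truth class.

    ``rho`` is the within-class correlation between the dm and abus scores;
    rho < 1 makes the modalities complementary, which is what gives weighted
    fusion room to beat either modality alone.
    """

    mean_dm: float
    sd_dm: float
    mean_abus: float
    sd_abus: float
    rho: float

    def mean(self, modality: str) -> float:
        return {"dm": self.mean_dm, "abus": self.mean_abus}[modality]

    def sd(self, modality: str) -> float:
        return {"dm": self.sd_dm, "abus": self.sd_abus}[modality]


@dataclass(frozen=True)
class BinormalModelSpec:
    """Per-class bivariate score models for the three truth classes."""

    malignant: ClassScoreModel
    benign: ClassScoreModel
    normal: ClassScoreModel

    def __post_init__(self) -> None:
        for cls in CLASSES:
            m: ClassScoreModel = getattr(self, cls)
            for mod in MODALITIES:
                if not m.sd(mod) > 0:
                    raise ConfigurationError(
                        f"standard deviation for class {cls!r}, modality {mod!r} "
                        f"must be > 0, got {m.sd(mod)}"
                    )
            if not abs(m.rho) <= 1:
                raise ConfigurationError(
                    f"inter-modality correlation for class {cls!r} must satisfy "
                    f"|rho| <= 1, got {m.rho}"
                )

    def for_class(self, cls: str) -> ClassScoreModel:
        if cls not in CLASSES:
            raise ConfigurationError(f"unknown truth class {cls!r}")
        return getattr(self, cls)


#: Default score model.  Unit-variance classes with means chosen so the
#: analytic single-modality AUCs against the default 114:274 benign:normal
#: negative mixture are about 0.83 (dm) and 0.84 (abus) — the regime of
#: strong but imperfect standalone detectors — with moderate inter-modality
#: correlation (rho = 0.3), i.e. genuinely complementary modalities.
DEFAULT_MODEL = BinormalModelSpec(
    malignant=ClassScoreModel(1.50, 1.0, 1.55, 1.0, 0.3),
    benign=ClassScoreModel(0.50, 1.0, 0.50, 1.0, 0.3),
    normal=ClassScoreModel(0.00, 1.0, 0.00, 1.0, 0.3),
)


@dataclass(frozen=True)
class ReaderProfile:
    """A simulated reader: one distribution over BI-RADS categories per class.

    ``probs`` maps each truth class to a length-7 probability vector over
    :data:`BIRADS_CATEGORIES`.
    """

    probs: Mapping[str, Sequence[float]]
    name: str = "reader"

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for cls in CLASSES:
            if cls not in self.probs:
                raise ConfigurationError(f"profile {self.name!r} lacks class {cls!r}")
            p = np.asarray(self.probs[cls], dtype=float)
            if p.shape != (len(BIRADS_CATEGORIES),):
                raise ConfigurationError(
                    f"profile {self.name!r}, class {cls!r}: expected "
                    f"{len(BIRADS_CATEGORIES)} probabilities, got shape {p.shape}"
                )
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"profile {self.name!r}, class {cls!r}: probabilities must be "
                    f"non-negative and sum to 1 (sum = {p.sum()!r})"
                )
            clean[cls] = p
        object.__setattr__(self, "probs", clean)

    def recall_probability(self, cls: str, threshold_category: str = "3") -> float:
        """Probability this reader assigns category >= threshold to class ``cls``."""
        t = CATEGORY_RANK[threshold_category]
        return float(np.asarray(self.probs[cls])[t:].sum())


def profile_from_operating_point(
    sensitivity: float,
    specificity: float,
    threshold_category: str = "3",
    name: str = "reader",
) -> ReaderProfile:
    """Build a reader profile hitting a target operating point.

    The returned profile satisfies, exactly in expectation at the given recall
    threshold: P(category >= threshold | malignant) = ``sensitivity`` and
    P(category >= threshold | benign or normal) = 1 - ``specificity``.  Benign
    and normal share a distribution so the pooled specificity is calibrated
    regardless of the benign:normal mix.

    Within the recall / no-recall halves the mass is spread over categories
    with fixed shapes (malignant recalls skewed toward high categories,
    non-malignant recalls concentrated just above threshold), which only
    matters for majority voting on categories, not for recall decisions.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ConfigurationError("sensitivity and specificity must lie in [0, 1]")
    if threshold_category not in CATEGORY_RANK:
        raise ConfigurationError(f"unknown category {threshold_category!r}")
    t = CATEGORY_RANK[threshold_category]
    n_cat = len(BIRADS_CATEGORIES)
    n_hi, n_lo = n_cat - t, t

    def _shaped(mass: float, n: int, ratio: float) -> np.ndarray:
        # geometric shape; ratio > 1 puts more mass on higher categories
        if n == 0:
            return np.zeros(0)
        w = ratio ** np.arange(n)
        return mass * w / w.sum()

    def _vec(recall_mass: float, hi_ratio: float, lo_ratio: float) -> np.ndarray:
        return np.concatenate(
            [_shaped(1.0 - recall_mass, n_lo, lo_ratio), _shaped(recall_mass, n_hi, hi_ratio)]
        )

    probs = {
        # malignant recalls climb toward category 5; misses sit near threshold
        "malignant": _vec(sensitivity, hi_ratio=1.3, lo_ratio=1.5),
        # false recalls hug the threshold; correct non-recalls skew to category 1
        "benign": _vec(1.0 - specificity, hi_ratio=0.45, lo_ratio=0.8),
        "normal": _vec(1.0 - specificity, hi_ratio=0.45, lo_ratio=0.8),
    }
    return ReaderProfile(probs=probs, name=name)


#: Default simulated panel: two DM readers and two ABUS readers whose
#: single-reader operating points (at recall threshold category 3) emulate
#: experienced screening radiologists — DM readers around sens 0.78/0.79 with
#: spec 0.45/0.57, ABUS readers around sens 0.94/0.85 with spec 0.22/0.38.
DEFAULT_READER_NAMES = (
    "reader_dm_1",
    "reader_dm_2",
    "reader_abus_1",
    "reader_abus_2",
)

DEFAULT_READER_PROFILES = (
    profile_from_operating_point(0.778, 0.454, name="reader_dm_1"),
    profile_from_operating_point(0.792, 0.571, name="reader_dm_2"),
    profile_from_operating_point(0.942, 0.221, name="reader_abus_1"),
    profile_from_operating_point(0.854, 0.379, name="reader_abus_2"),
)


def _class_cov(m: ClassScoreModel) -> np.ndarray:
    c = m.rho * m.sd_dm * m.sd_abus
    return np.array([[m.sd_dm**2, c], [c, m.sd_abus**2]])


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    model: BinormalModelSpec = DEFAULT_MODEL,
) -> pd.DataFrame:
    """Draw a synthetic case table.

    Returns a DataFrame with exactly ``config`` rows per class; each case's
    (dm, abus) score pair is drawn from its class's bivariate Gaussian.
    Identical (config, model) — including the seed — yields an identical table.
    """
    if config.n_total < 1:
        raise ConfigurationError("cohort must contain at least one case")
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for cls in CLASSES:
        n = config.counts[cls]
        if n == 0:
            continue
        m = model.for_class(cls)
        scores = rng.multivariate_normal(
            mean=[m.mean_dm, m.mean_abus], cov=_class_cov(m), size=n
        )
        frames.append(
            pd.DataFrame(
                {
                    "case_id": [f"case_{offset + i + 1:04d}" for i in range(n)],
                    "truth_class": cls,
                    "score_dm": scores[:, 0],
                    "score_abus": scores[:, 1],
                }
            )
        )
        offset += n
    table = pd.concat(frames, ignore_index=True)
    validate_case_table(table)
    return table


def analytic_auc(
    model: BinormalModelSpec,
    modality: str = "dm",
    positive_class: str = "malignant",
    negative_classes: Sequence[str] = ("benign", "normal"),
    negative_weights: Sequence[float] | None = None,
    config: CohortConfig | None = None,
) -> float:
    """Closed-form AUC of one modality under the Gaussian score model.

    For positive scores ~ N(mu1, s1^2) and a mixture of negative classes with
    weights w_c and scores ~ N(mu_c, s_c^2),

        AUC = sum_c w_c * Phi((mu1 - mu_c) / sqrt(s1^2 + s_c^2)).

    Mixture weights come from ``negative_weights``, or proportional to the
    class counts of ``config``; with neither, the negatives are weighted
    equally.
    """
    if modality not in MODALITIES:
        raise ConfigurationError(f"unknown modality {modality!r}")
    if len(negative_classes) == 0:
        raise ConfigurationError("at least one negative class is required")
    if negative_weights is not None:
        w = np.asarray(negative_weights, dtype=float)
        if w.shape != (len(negative_classes),) or (w < 0).any() or w.sum() <= 0:
            raise ConfigurationError("negative_weights must be non-negative and sum > 0")
    elif config is not None:
        w = np.array([config.counts[c] for c in negative_classes], dtype=float)
        if w.sum() <= 0:
            raise ConfigurationError("config has no cases in the negative classes")
    else:
        w = np.ones(len(negative_classes))
    w = w / w.sum()

    pos = model.for_class(positive_class)
    mu1, s1 = pos.mean(modality), pos.sd(modality)
    total = 0.0
    for weight, cls in zip(w, negative_classes):
        neg = model.for_class(cls)
        mu0, s0 = neg.mean(modality), neg.sd(modality)
        total += weight * norm.cdf((mu1 - mu0) / math.sqrt(s1**2 + s0**2))
    return float(total)


def generate_reader_scores(
    cases: pd.DataFrame,
    profiles: Sequence[ReaderProfile],
    seed: int,
    names: Sequence[str] | None = None,
    stream_offset: int = 0,
) -> pd.DataFrame:
    """Append one ordinal BI-RADS column per reader profile.

    Each case's category is drawn independently from the profile's
    distribution conditional on the case's truth class.  Reader ``i`` draws
    from a dedicated RNG sub-stream keyed by ``stream_offset + i``, so adding
    a reader (or changing the offset) never perturbs earlier columns.
    """
    validate_case_table(cases)
    if names is None:
        names = [p.name if p.name != "reader" else f"reader_{i + 1}" for i, p in enumerate(profiles)]
    if len(names) != len(profiles):
        raise ConfigurationError("names and profiles must have equal length")
    out = cases.copy()
    classes = cases["truth_class"].to_numpy()
    cats = np.asarray(BIRADS_CATEGORIES, dtype=object)
    for i, (profile, name) in enumerate(zip(profiles, names)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(stream_offset + i,))
        )
        col = np.empty(len(cases), dtype=object)
        for cls in CLASSES:
            mask = classes == cls
            n = int(mask.sum())
            if n:
                col[mask] = cats[rng.choice(len(cats), size=n, p=profile.probs[cls])]
        out[name] = col
    return out


def observer_subcohort(
    cases: pd.DataFrame,
    n_benign: int = 30,
    n_normal: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified reading subcohort: all malignant cases plus seeded random
    samples of benign and normal cases (default 30 and 80, giving roughly two
    normals per cancer and a ~20% benign share)."""
    validate_case_table(cases)
    rng = np.random.default_rng(seed)
    parts = [cases[cases["truth_class"] == "malignant"]]
    for cls, n in (("benign", n_benign), ("normal", n_normal)):
        pool = cases[cases["truth_class"] == cls]
        if n > len(pool):
            raise ConfigurationError(
                f"requested {n} {cls} cases but the cohort has only {len(pool)}"
            )
        idx = np.sort(rng.choice(len(pool), size=n, replace=False))
        parts.append(pool.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def validate_case_table(table: pd.DataFrame) -> None:
    """Enforce the case-table contract; raise a descriptive error otherwise."""
    missing = [c for c in CASE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"case table lacks mandatory columns: {missing}")
    dup = table["case_id"][table["case_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate case_id values: {sorted(set(dup))}")
    bad = set(table["truth_class"]) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown truth_class values: {sorted(bad)}")
    for col in ("score_dm", "score_abus"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            rows = table.index[vals.isna()].tolist()
            raise ValueError(f"non-numeric {col} values at rows {rows}")
    reader_cols = [c for c in table.columns if c not in CASE_TABLE_COLUMNS]
    for col in reader_cols:
        bad = set(table[col].astype(str)) - set(BIRADS_CATEGORIES)
        if bad:
            raise ValueError(
                f"reader column {col!r} contains unknown categories: {sorted(bad)}"
            )
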