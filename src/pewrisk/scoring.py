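"""Component scorers and the sklearn-style risk-score estimator.

The score sums six 0-3 sub-scores (BMI, functional capacity, dialysis
vintage, serum albumin, serum ferritin, comorbidity count) into a 0-18
total, dichotomized into low risk (total < threshold) and high risk
(total >= threshold); the validated threshold is 6.

All single-component scorers accept scalars or array-likes and are exact
step functions of their input; no imputation is ever performed, missing
scoring inputs raise :class:`MissingDataError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import (
    COMORBIDITIES,
    DEFAULT_BANDS,
    DEFAULT_THRESHOLD,
    FUNCTIONAL_LEVELS,
    ScoreBands,
    _as_array,
)


class InvalidInputError(ValueError):
    """An input outside its physiologic/definitional domain."""


class MissingDataError(ValueError):
    """A required scoring input is absent; names the offending field."""


@dataclass(frozen=True)
class PatientSnapshot:
    """One patient's covariates, labs and outcomes at a scoring time point.

    Units: age and vintage in years, BMI in kg/m2, albumin and hemoglobin
    in g/L, ferritin in ug/L; Kt/V dimensionless.
    """

    patient_id: str
    sex: str  # "male" | "female"
    age: float
    bmi: float
    functional_capacity: str
    vintage: float
    albumin: float
    ferritin: float
    comorbidities: frozenset[str] = frozenset()
    marital_status: str = "married"
    on_epo: bool = False
    hemoglobin: float | None = None
    ktv: float | None = None
    outcome_vascular_admission: bool = False
    outcome_nonvascular_admission: bool = False
    outcome_death: bool = False
    quarter: int | None = None

    def __post_init__(self):
        extra = set(self.comorbidities) - set(COMORBIDITIES)
        if extra:
            raise InvalidInputError(f"unknown comorbidities {sorted(extra)}")
        if self.functional_capacity not in FUNCTIONAL_LEVELS:
            raise InvalidInputError(
                f"functional_capacity {self.functional_capacity!r} not one of {FUNCTIONAL_LEVELS}"
            )


@dataclass(frozen=True)
class ComponentScores:
    bmi_score: int
    functional_score: int
    vintage_score: int
    albumin_score: int
    ferritin_score: int
    comorbidity_score: int

    @property
    def total(self) -> int:
        return (
            self.bmi_score
            + self.functional_score
            + self.vintage_score
            + self.albumin_score
            + self.ferritin_score
            + self.comorbidity_score
        )

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.bmi_score,
            self.functional_score,
            self.vintage_score,
            self.albumin_score,
            self.ferritin_score,
            self.comorbidity_score,
        )


@dataclass(frozen=True)
class RiskResult:
    total: int
    threshold: int = DEFAULT_THRESHOLD
    category: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "category", "high" if self.total >= self.threshold else "low")


def _check_positive(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise InvalidInputError(f"{name} must be positive and finite")


def score_bmi(bmi, bands: ScoreBands = DEFAULT_BANDS):
    """Score BMI (kg/m2): >=20 -> 0, [18,20) -> 1, [16,18) -> 2, <16 -> 3."""
    arr, scalar = _as_array(bmi)
    _check_positive(arr, "bmi")
    s = 3 - np.searchsorted(bands.bmi_cuts, arr, side="right")
    return int(s) if scalar else s.astype(int)


def score_albumin(albumin, bands: ScoreBands = DEFAULT_BANDS):
    """Score serum albumin (g/L): >=35 -> 0, [32,35) -> 1, [28,32) -> 2, <28 -> 3."""
    arr, scalar = _as_array(albumin)
    _check_positive(arr, "albumin")
    s = 3 - np.searchsorted(bands.albumin_cuts, arr, side="right")
    return int(s) if scalar else s.astype(int)


def score_ferritin(ferritin, bands: ScoreBands = DEFAULT_BANDS):
    """Score serum ferritin (ug/L): <=700 -> 0, (700,800] -> 1, (800,1000] -> 2, >1000 -> 3."""
    arr, scalar = _as_array(ferritin)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("ferritin must be non-negative and finite")
    s = np.searchsorted(bands.ferritin_cuts, arr, side="left")
    return int(s) if scalar else s.astype(int)


def score_vintage(years, bands: ScoreBands = DEFAULT_BANDS):
    """Score years on hemodialysis: <1 -> 0, [1,3) -> 1, [3,4] -> 2, >4 -> 3.

    The middle band is closed at both ends: exactly 3 years and exactly 4
    years both score 2.
    """
    arr, scalar = _as_array(years)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("vintage must be non-negative and finite")
    v1, v2, v3 = bands.vintage_cuts
    s = np.where(arr > v3, 3, np.searchsorted([v1, v2], arr, side="right"))
    return int(s) if scalar else s.astype(int)


def score_functional(level, bands: ScoreBands = DEFAULT_BANDS):
    """Score functional capacity: normal 0 ... bed/chair-bound 3."""
    if isinstance(level, str):
        try:
            return bands.functional_points[level]
        except KeyError:
            raise InvalidInputError(
                f"unknown functional capacity {level!r}; expected one of {FUNCTIONAL_LEVELS}"
            ) from None
    return np.array([score_functional(lv, bands) for lv in level], dtype=int)


def score_comorbidity(count, bands: ScoreBands = DEFAULT_BANDS):
    """Score the comorbidity count: <=1 -> 0, 2 -> 1, 3 -> 2, >=4 -> 3.

    Zero comorbidities sits below the least-severe band and scores 0.
    """
    arr = np.asarray(count)
    scalar = arr.ndim == 0
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.floor(arr)):
        raise InvalidInputError("comorbidity count must be a non-negative integer")
    keys = np.array(sorted(bands.comorbidity_points))
    pts = np.array([bands.comorbidity_points[k] for k in keys])
    idx = np.clip(np.searchsorted(keys, arr, side="right") - 1, 0, len(keys) - 1)
    s = np.where(arr < keys[0], pts[0], pts[idx])
    return int(s) if scalar else s.astype(int)


def compute_score(snapshot: PatientSnapshot, bands: ScoreBands = DEFAULT_BANDS) -> ComponentScores:
    """Score one patient snapshot; raises MissingDataError naming any absent field."""
    for name in ("bmi", "functional_capacity", "vintage", "albumin", "ferritin"):
        value = getattr(snapshot, name)
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            raise MissingDataError(f"missing scoring input: {name}")
    return ComponentScores(
        bmi_score=score_bmi(snapshot.bmi, bands),
        functional_score=score_functional(snapshot.functional_capacity, bands),
        vintage_score=score_vintage(snapshot.vintage, bands),
        albumin_score=score_albumin(snapshot.albumin, bands),
        ferritin_score=score_ferritin(snapshot.ferritin, bands),
        comorbidity_score=score_comorbidity(len(snapshot.comorbidities), bands),
    )


def classify(total: int, threshold: int = DEFAULT_THRESHOLD) -> RiskResult:
    """Dichotomize a total score: high risk iff total >= threshold."""
    if not 0 <= total <= 18:
        raise InvalidInputError(f"total score {total} outside [0, 18]")
    if not 1 <= threshold <= 18:
        raise InvalidInputError(f"threshold {threshold} outside [1, 18]")
    return RiskResult(total=int(total), threshold=int(threshold))


AGGREGATION_POLICIES = ("baseline", "latest", "maximum", "mean_rounded")


def aggregate_quarters(
    scores: Sequence[ComponentScores], policy: str = "maximum"
) -> ComponentScores:
    """Collapse an ordered series of quarterly scores to one per patient.

    ``maximum`` (default, the most conservative screening rule) takes each
    component's worst value across quarters; ``baseline``/``latest`` take the
    first/last quarter; ``mean_rounded`` rounds each component's mean to the
    nearest integer (half away from zero).
    """
    if not scores:
        raise InvalidInputError("cannot aggregate an empty score series")
    if policy not in AGGREGATION_POLICIES:
        raise InvalidInputError(f"unknown aggregation policy {policy!r}")
    if policy == "baseline":
        return scores[0]
    if policy == "latest":
        return scores[-1]
    mat = np.array([s.as_tuple() for s in scores])
    if policy == "maximum":
        agg = mat.max(axis=0)
    else:  # mean_rounded
        agg = np.floor(mat.mean(axis=0) + 0.5).astype(int)
    return ComponentScores(*[int(x) for x in agg])


# ---------------------------------------------------------------------------
# DataFrame-level scoring (vectorized) and the sklearn estimator
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "bmi_score",
    "functional_score",
    "vintage_score",
    "albumin_score",
    "ferritin_score",
    "comorbidity_score",
]

REQUIRED_INPUTS = {
    "bmi": "bmi",
    "functional": "functional_capacity",
    "vintage_years": "vintage",
    "albumin_gL": "albumin",
    "ferritin_ugL": "ferritin",
}


def _functional_codes(col: pd.Series) -> np.ndarray:
    """Accept the four level names or integer codes 0..3."""
    if pd.api.types.is_numeric_dtype(col):
        codes = col.to_numpy()
        if np.any(~np.isin(codes, [0, 1, 2, 3])):
            raise InvalidInputError("functional codes must be in 0..3")
        return codes.astype(int)
    return score_functional(col.tolist())


def score_frame(df: pd.DataFrame, bands: ScoreBands = DEFAULT_BANDS) -> pd.DataFrame:
    """Vectorized scoring of a cohort table (data-dictionary columns).

    Returns a DataFrame with the six component scores and ``total``,
    indexed like ``df``.
    """
    for col, label in REQUIRED_INPUTS.items():
        if col not in df.columns:
            raise MissingDataError(f"missing scoring input column: {col}")
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise MissingDataError(f"missing {label} for rows {rows[:10]}")
    comorbid_count = df[["dm", "htn", "ihd", "cvd"]].astype(int).sum(axis=1).to_numpy()
    out = pd.DataFrame(
        {
            "bmi_score": score_bmi(df["bmi"].to_numpy(), bands),
            "functional_score": _functional_codes(df["functional"]),
            "vintage_score": score_vintage(df["vintage_years"].to_numpy(), bands),
            "albumin_score": score_albumin(df["albumin_gL"].to_numpy(), bands),
            "ferritin_score": score_ferritin(df["ferritin_ugL"].to_numpy(), bands),
            "comorbidity_score": score_comorbidity(comorbid_count, bands),
        },
        index=df.index,
    )
    out["total"] = out[SCORE_COLUMNS].sum(axis=1)
    return out


class HashmiScorer(BaseEstimator, TransformerMixin):
    """Rule-based six-component PEW risk scorer, sklearn style.

    A stateless, fully specified clinical rule: ``fit`` only validates the
    configuration and records the input schema, so the estimator composes
    with sklearn pipelines and model selection (e.g. threshold sweeps via
    ``GridSearchCV`` with a downstream metric).

    Parameters
    ----------
    threshold : int, default 6
        Total score at or above which a patient is high risk.
    bands : ScoreBands or None
        Band edges; None means the published grid.
    aggregation : str, default "maximum"
        Policy for collapsing quarterly rows of one patient.

    Attributes
    ----------
    bands_ : ScoreBands
        The resolved band grid.
    threshold_ : int
    feature_names_in_ : ndarray of str
    """

    def __init__(self, threshold: int = DEFAULT_THRESHOLD, bands: ScoreBands | None = None,
                 aggregation: str = "maximum"):
        self.threshold = threshold
        self.bands = bands
        self.aggregation = aggregation

    def fit(self, X: pd.DataFrame, y=None):
        if not 1 <= int(self.threshold) <= 18:
            raise InvalidInputError(f"threshold {self.threshold} outside [1, 18]")
        if self.aggregation not in AGGREGATION_POLICIES:
            raise InvalidInputError(f"unknown aggregation policy {self.aggregation!r}")
        missing = [c for c in REQUIRED_INPUTS if c not in X.columns]
        if missing:
            raise MissingDataError(f"missing scoring input columns: {missing}")
        self.bands_ = self.bands if self.bands is not None else DEFAULT_BANDS
        self.threshold_ = int(self.threshold)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _collapse(self, X: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
        if "quarter" not in X.columns or "patient_id" not in X.columns:
            return scores
        if X["patient_id"].is_unique:
            return scores
        scores = scores.copy()
        scores["patient_id"] = X["patient_id"].to_numpy()
        if self.aggregation == "maximum":
            agg = scores.groupby("patient_id", sort=False)[SCORE_COLUMNS].max()
        elif self.aggregation == "baseline":
            agg = scores.groupby("patient_id", sort=False)[SCORE_COLUMNS].first()
        elif self.aggregation == "latest":
            agg = scores.groupby("patient_id", sort=False)[SCORE_COLUMNS].last()
        else:
            agg = (
                scores.groupby("patient_id", sort=False)[SCORE_COLUMNS]
                .mean()
                .add(0.5)
                .apply(np.floor)
                .astype(int)
            )
        agg["total"] = agg[SCORE_COLUMNS].sum(axis=1)
        return agg.reset_index()

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Component scores + total, one row per patient (quarters collapsed)."""
        self._check_fitted()
        scores = score_frame(X, self.bands_)
        return self._collapse(X, scores)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Risk category per patient: 'low' or 'high'."""
        totals = self.transform(X)["total"].to_numpy()
        return np.where(totals >= self.threshold_, "high", "low")

    def _check_fitted(self):
        if not hasattr(self, "bands_"):
            raise RuntimeError("HashmiScorer is not fitted; call fit(X) first")

    def get_feature_names_out(self, input_features=None):
        return np.asarray(SCORE_COLUMNS + ["total"], dtype=object)
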