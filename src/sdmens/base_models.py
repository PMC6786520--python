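"""Base habitat-suitability models: ingestion and dichotomization.

Published suitability models arrive either as regular lon/lat grids of
scores or as county-level tables; they are never refit here. Continuous
models (scores in [0, 1]) are converted to binary presence/absence calls
by scanning cutoffs on a 0.01 grid and keeping the cutoff that maximizes
sensitivity + specificity on the training labels — equivalently the
maximum of Youden's J / the "adjusted accuracy" (their average), since the
two objectives are monotone transforms of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import MetricSet, confusion_metrics_arrays

__all__ = [
    "SuitabilityGrid",
    "BaseModelPrediction",
    "grid_to_county",
    "ThresholdDichotomizer",
    "select_cutoff",
    "dichotomize",
]


@dataclass
class SuitabilityGrid:
    """Regular lon/lat grid of suitability scores.

    ``values`` has shape (len(lat_axis), len(lon_axis)); axes hold cell
    centers in degrees and must be strictly monotone. Missing cells are NaN.
    """

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, ax in (("lon_axis", self.lon_axis), ("lat_axis", self.lat_axis)):
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D vector")
            d = np.diff(ax)
            if ax.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        if self.values.shape != (self.lat_axis.size, self.lon_axis.size):
            raise ValueError("values shape must be (n_lat, n_lon)")
        if np.all(np.isnan(self.values)):
            raise ValueError("grid contains no data")


def _nearest_index(axis: np.ndarray, v: float) -> int | None:
    """Index of the cell center nearest v; ties go to the lower index.

    Returns None when v falls outside the axis extent (cell centers padded
    by half the edge spacing).
    """
    asc = axis if axis.size < 2 or axis[1] > axis[0] else axis[::-1]
    flipped = asc is not axis
    if asc.size == 1:
        lo_pad = hi_pad = 0.5
    else:
        lo_pad = (asc[1] - asc[0]) / 2.0
        hi_pad = (asc[-1] - asc[-2]) / 2.0
    if v < asc[0] - lo_pad or v > asc[-1] + hi_pad:
        return None
    j = int(np.searchsorted(asc, v))
    if j == 0:
        k = 0
    elif j == asc.size:
        k = asc.size - 1
    else:
        # tie at the exact midpoint goes to the lower index
        k = j - 1 if v - asc[j - 1] <= asc[j] - v else j
    return (axis.size - 1 - k) if flipped else k


def grid_to_county(grid: SuitabilityGrid, counties: pd.DataFrame) -> pd.Series:
    """Extract per-county scores: the grid cell nearest each centroid.

    Centroids outside the grid extent get NaN, with one summary warning.
    """
    scores = np.full(len(counties), np.nan)
    n_outside = 0
    for i, (la, lo) in enumerate(
        zip(counties["lat"].to_numpy(dtype=float), counties["lon"].to_numpy(dtype=float))
    ):
        ilat = _nearest_index(grid.lat_axis, la)
        ilon = _nearest_index(grid.lon_axis, lo)
        if ilat is None or ilon is None:
            n_outside += 1
            continue
        scores[i] = grid.values[ilat, ilon]
    if n_outside:
        warnings.warn(
            f"{n_outside} county centroids fall outside the grid extent; scores set to missing",
            stacklevel=2,
        )
    return pd.Series(scores, index=counties["county_id"].to_numpy(), name="score")


class ThresholdDichotomizer(BaseEstimator, ClassifierMixin):
    """Dichotomize continuous suitability scores by exhaustive cutoff search.

    Evaluates every cutoff c in {0, step, 2*step, ..., 1}; a county is
    called present iff score >= c. The fitted cutoff maximizes
    sensitivity(c) + specificity(c) on the training labels, ties broken
    toward the smallest cutoff (the most sensitive choice).

    Parameters
    ----------
    step : float, default 0.01
        Cutoff grid increment.

    Attributes
    ----------
    cutoff_ : float
        Selected cutoff.
    trace_ : DataFrame
        Columns ``cutoff``, ``sensitivity``, ``specificity`` over the whole
        grid (the cutoff-selection curve).
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(self, step: float = 0.01):
        self.step = step

    def fit(self, X, y):
        score = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=int).reshape(-1)
        if score.shape != y.shape:
            raise ValueError("X and y must have the same length")
        keep = ~np.isnan(score)
        score, y = score[keep], y[keep]
        if score.size == 0:
            raise ValueError("all scores are missing")
        pos = y == 1
        neg = y == 0
        if not pos.any() or not neg.any():
            raise ValueError("training labels must contain both classes")
        if np.any(score < 0) or np.any(score > 1):
            warnings.warn("scores outside [0, 1] clamped before cutoff search", stacklevel=2)
            score = np.clip(score, 0.0, 1.0)

        n_steps = int(round(1.0 / self.step))
        grid = np.round(np.arange(n_steps + 1) * self.step, 10)
        calls = score[None, :] >= grid[:, None]  # (n_cutoffs, n_counties)
        sens = calls[:, pos].mean(axis=1)
        spec = 1.0 - calls[:, neg].mean(axis=1)
        objective = sens + spec
        # smallest cutoff on the optimal plateau; the 1e-12 slack absorbs
        # float non-associativity (true objective gaps are >= 1/(P*N))
        best = int(np.flatnonzero(objective >= objective.max() - 1e-12)[0])
        self.cutoff_ = float(grid[best])
        self.trace_ = pd.DataFrame(
            {"cutoff": grid, "sensitivity": sens, "specificity": spec}
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        score = np.asarray(X, dtype=float).reshape(-1)
        out = np.where(np.isnan(score), np.nan, (score >= self.cutoff_).astype(float))
        return out

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"binary_only": True}


def select_cutoff(score: pd.Series, labels: pd.DataFrame, step: float = 0.01):
    """Fit a ThresholdDichotomizer on training-labeled counties.

    Returns ``(cutoff, trace)``. ``labels`` must carry ``split``; only
    ``split == "train"`` counties enter the search.
    """
    train = labels[(labels["split"] == "train") & labels["label"].notna()]
    aligned = score.reindex(train["county_id"].to_numpy())
    est = ThresholdDichotomizer(step=step).fit(
        aligned.to_numpy(dtype=float), train["label"].to_numpy(dtype=int)
    )
    return est.cutoff_, est.trace_


@dataclass
class BaseModelPrediction:
    """One base model's per-county scores and (after dichotomization) calls."""

    model_name: str
    kind: str  # "continuous" or "binary"
    score: pd.Series
    cutoff: float | None = None
    binary_call: pd.Series | None = None
    training_metrics: MetricSet | None = None
    trace: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError("kind must be 'continuous' or 'binary'")


def dichotomize(
    model: BaseModelPrediction, labels: pd.DataFrame, step: float = 0.01
) -> BaseModelPrediction:
    """Populate binary calls for one base model.

    Continuous models get a cutoff from the training labels and calls
    ``score >= cutoff`` for every county (labeled or not); binary models
    pass through unchanged. Training-set confusion metrics are attached.
    """
    score = model.score.astype(float)
    if model.kind == "binary":
        calls = score.copy()
        cutoff, trace = model.cutoff, model.trace
    else:
        if np.any(score.to_numpy() < 0) or np.any(score.to_numpy() > 1):
            warnings.warn(
                f"model {model.model_name!r}: scores outside [0, 1] clamped", stacklevel=2
            )
            score = score.clip(0.0, 1.0)
        cutoff, trace = select_cutoff(score, labels, step=step)
        calls = pd.Series(
            np.where(score.isna(), np.nan, (score >= cutoff).astype(float)),
            index=score.index,
            name=model.model_name,
        )
    train = labels[(labels["split"] == "train") & labels["label"].notna()]
    aligned = calls.reindex(train["county_id"].to_numpy())
    ok = aligned.notna().to_numpy()
    tm = confusion_metrics_arrays(
        aligned.to_numpy(dtype=float)[ok].astype(int),
        train["label"].to_numpy(dtype=int)[ok],
    )
    return BaseModelPrediction(
        model_name=model.model_name,
        kind=model.kind,
        score=model.score,
        cutoff=cutoff,
        binary_call=calls,
        training_metrics=tm,
        trace=trace,
    )
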