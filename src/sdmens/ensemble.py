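"""Accuracy-weighted ensembling and probability calibration.

The ensemble replaces each base model's binary county call with an
estimate of the probability that the call is a true positive: a positive
call contributes the model's in-sample PPV, a negative call contributes
1 − NPV. Averaging these substituted values across models yields a raw
ensemble score in [0, 1] in which reliable models dominate the consensus.
The raw score is then calibrated against the training labels with a
binomial generalized additive model (penalized cubic spline on the raw
score, logit link), so the final county-level prediction is a calibrated
probability of presence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import confusion_metrics_arrays

__all__ = ["AccuracyWeightedEnsemble", "substitute_and_average"]


def substitute_and_average(
    calls: pd.DataFrame, weights: dict[str, tuple[float | None, float | None]]
) -> pd.Series:
    """Raw ensemble score: mean of per-model PPV / 1−NPV substitutions.

    Parameters
    ----------
    calls
        Counties x models table of binary calls (NaN where a model does not
        cover a county).
    weights
        Per-model ``(ppv, npv)``. Models with an undefined PPV or NPV are
        excluded with a warning.

    Counties with no call from any retained model get a missing raw score.
    """
    usable: list[str] = []
    for name in calls.columns:
        ppv, npv = weights[name]
        if ppv is None or npv is None or np.isnan(ppv) or np.isnan(npv):
            warnings.warn(
                f"model {name!r} excluded from the ensemble: undefined PPV or NPV",
                stacklevel=2,
            )
        else:
            usable.append(name)
    if not usable:
        raise ValueError("no base model has defined PPV and NPV")
    contrib = pd.DataFrame(index=calls.index, columns=usable, dtype=float)
    for name in usable:
        ppv, npv = weights[name]
        c = calls[name].astype(float)
        contrib[name] = np.where(c.isna(), np.nan, np.where(c == 1, ppv, 1.0 - npv))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        raw = contrib.mean(axis=1, skipna=True)
    raw.name = "raw_score"
    return raw


@dataclass
class _Calibration:
    """Fitted smooth map from raw score to probability, with boundary extension."""

    kind: str  # "gam", "glm" or "constant"
    result: object | None
    x_min: float
    x_max: float
    constant: float | None = None
    edf: float | None = None

    def predict(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        out = np.full(raw.shape, np.nan)
        ok = ~np.isnan(raw)
        if self.kind == "constant":
            out[ok] = self.constant
            return out
        x = np.clip(raw[ok], self.x_min, self.x_max)  # constant beyond training range
        if self.kind == "gam":
            p = self.result.predict(np.ones((x.size, 1)), exog_smooth=x[:, None])
        else:
            p = self.result.predict(sm.add_constant(x, has_constant="add"))
        out[ok] = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
        return out


class AccuracyWeightedEnsemble(BaseEstimator, ClassifierMixin):
    """Calibrated accuracy-weighted ensemble of binary suitability models.

    ``fit`` takes the counties x models matrix of binary training calls and
    the presence (1) / pseudo-absence (0) labels. It estimates each model's
    in-sample PPV and NPV, forms the substituted-and-averaged raw score,
    and fits the binomial spline calibration. ``predict_proba`` maps new
    call matrices to calibrated probabilities of presence; raw scores
    outside the training range are predicted at the boundary value.

    Parameters
    ----------
    spline_df : int, default 10
        Basis dimension of the penalized cubic calibration spline.
    degree : int, default 3
        Spline degree.
    alphas : sequence of float, optional
        Candidate penalty weights; the one minimizing AIC is kept. Default
        is a log-spaced grid from 1e-4 to 1e4.
    threshold : float, default 0.5
        Probability cutoff for ``predict`` (present iff p >= threshold).
    model_names : sequence of str, optional
        Names for the call-matrix columns; defaults to the DataFrame
        columns or ``model_0 ... model_{K-1}``.

    Attributes
    ----------
    ppv_, npv_ : ndarray of shape (n_models,)
        In-sample predictive values (NaN where undefined).
    weights_ : dict
        ``{model_name: (ppv, npv)}``.
    edf_ : float
        Effective degrees of freedom of the calibration fit (trace of the
        hat matrix, intercept included).
    calibration_ : _Calibration
        The fitted raw-score -> probability map.
    classes_ : ndarray
        ``[0, 1]``.
    """

    def __init__(
        self,
        spline_df: int = 10,
        degree: int = 3,
        alphas=None,
        threshold: float = 0.5,
        model_names=None,
    ):
        self.spline_df = spline_df
        self.degree = degree
        self.alphas = alphas
        self.threshold = threshold
        self.model_names = model_names

    # ---- internals ---------------------------------------------------

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D counties x models call matrix")
        names = self.model_names or [f"model_{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X, columns=list(names))

    def _fit_calibration(self, raw: np.ndarray, y: np.ndarray) -> _Calibration:
        x_min, x_max = float(raw.min()), float(raw.max())
        if np.unique(raw).size < 2:
            warnings.warn(
                "constant raw score; calibration falls back to the empirical class rate",
                stacklevel=2,
            )
            return _Calibration("constant", None, x_min, x_max, constant=float(y.mean()))
        alphas = self.alphas if self.alphas is not None else np.logspace(-4, 4, 9)
        bs = BSplines(raw[:, None], df=[self.spline_df], degree=[self.degree])
        intercept = np.ones((raw.size, 1))
        design = np.column_stack([intercept, bs.basis])
        pen = bs.penalty_matrices[0]
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a in alphas:
                try:
                    res = GLMGam(
                        y,
                        intercept,
                        smoother=bs,
                        alpha=np.array([float(a)]),
                        family=sm.families.Binomial(),
                    ).fit()
                except Exception:
                    continue
                if not np.all(np.isfinite(res.params)):
                    continue
                # edf = tr[(X'WX + S)^+ X'WX] at the converged IRLS weights;
                # statsmodels' own hat-matrix trace is numerically unstable
                # on designs with few distinct raw-score values
                mu = np.clip(np.asarray(res.fittedvalues, dtype=float), 1e-10, 1 - 1e-10)
                w = mu * (1.0 - mu)
                xtwx = design.T @ (design * w[:, None])
                s_full = np.zeros_like(xtwx)
                s_full[1:, 1:] = float(a) * pen
                edf = float(np.trace(np.linalg.pinv(xtwx + s_full) @ xtwx))
                if not np.isfinite(edf) or edf <= 0:
                    continue
                aic = -2.0 * res.llf + 2.0 * edf
                if best is None or aic < best[0]:
                    best = (aic, res, edf)
        if best is not None:
            cal = _Calibration("gam", best[1], x_min, x_max)
            cal.edf = best[2]
            return cal
        # spline fit failed outright (e.g. degenerate design): plain logistic fit
        warnings.warn("spline calibration failed; using a plain logistic fit", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                y, sm.add_constant(raw, has_constant="add"), family=sm.families.Binomial()
            ).fit()
        return _Calibration("glm", res, x_min, x_max)

    # ---- sklearn API --------------------------------------------------

    def fit(self, X, y):
        calls = self._to_frame(X)
        y = np.asarray(y, dtype=int).reshape(-1)
        if len(calls) != y.size:
            raise ValueError("X and y must have the same number of counties")
        if not ((y == 0).any() and (y == 1).any()):
            raise ValueError("training labels must contain both classes")

        ppv = np.full(calls.shape[1], np.nan)
        npv = np.full(calls.shape[1], np.nan)
        for j, name in enumerate(calls.columns):
            c = calls[name].to_numpy(dtype=float)
            ok = ~np.isnan(c)
            if not ok.any():
                continue
            ms = confusion_metrics_arrays(c[ok].astype(int), y[ok])
            ppv[j] = np.nan if ms.ppv is None else ms.ppv
            npv[j] = np.nan if ms.npv is None else ms.npv
        self.ppv_, self.npv_ = ppv, npv
        self.weights_ = {
            name: (
                None if np.isnan(ppv[j]) else float(ppv[j]),
                None if np.isnan(npv[j]) else float(npv[j]),
            )
            for j, name in enumerate(calls.columns)
        }

        raw = substitute_and_average(calls, self.weights_).to_numpy(dtype=float)
        ok = ~np.isnan(raw)
        if not ok.any():
            raise ValueError("no county has a defined raw score")
        self.raw_score_ = raw
        self.calibration_ = self._fit_calibration(raw[ok], y[ok])
        if self.calibration_.kind == "gam":
            self.edf_ = float(self.calibration_.edf)
        elif self.calibration_.kind == "glm":
            self.edf_ = 2.0
        else:
            self.edf_ = 1.0
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = calls.shape[1]
        return self

    def raw_score(self, X) -> np.ndarray:
        """Substituted-and-averaged raw ensemble score for a call matrix."""
        check_is_fitted(self, "weights_")
        calls = self._to_frame(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return substitute_and_average(calls, self.weights_).to_numpy(dtype=float)

    def predict_proba(self, X):
        check_is_fitted(self, "calibration_")
        p = self.calibration_.predict(self.raw_score(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(np.isnan(p), np.nan, (p >= self.threshold).astype(float))

    # ---- persistence ---------------------------------------------------

    def to_json(self) -> str:
        """Serialize weights and the calibration map for exact reload.

        The smooth is stored as a dense lookup of the fitted map on a fine
        raw-score grid; reload reproduces predictions via interpolation at
        full float precision of the stored knots.
        """
        check_is_fitted(self, "calibration_")
        grid = np.linspace(self.calibration_.x_min, self.calibration_.x_max, 2001)
        payload = {
            "weights": self.weights_,
            "edf": self.edf_,
            "threshold": self.threshold,
            "calibration_grid": grid.tolist(),
            "calibration_values": self.calibration_.predict(grid).tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AccuracyWeightedEnsemble":
        payload = json.loads(text)
        est = cls(threshold=payload["threshold"])
        est.weights_ = {k: tuple(v) for k, v in payload["weights"].items()}
        est.ppv_ = np.array([v[0] for v in est.weights_.values()], dtype=float)
        est.npv_ = np.array([v[1] for v in est.weights_.values()], dtype=float)
        est.edf_ = payload["edf"]
        grid = np.asarray(payload["calibration_grid"], dtype=float)
        vals = np.asarray(payload["calibration_values"], dtype=float)

        class _Interp:
            kind = "interp"

            def __init__(self, g, v):
                self.g, self.v = g, v

            def predict(self, raw):
                raw = np.asarray(raw, dtype=float)
                out = np.full(raw.shape, np.nan)
                ok = ~np.isnan(raw)
                out[ok] = np.interp(raw[ok], self.g, self.v)
                return out

        est.calibration_ = _Interp(grid, vals)
        est.classes_ = np.array([0, 1])
        return est
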