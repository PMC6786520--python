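"""Evaluation of the calibrated ensemble: reliability, uncertainty, residuals.

Calibration is assessed by binning predicted probabilities into deciles
and comparing the predicted level with the observed presence frequency in
each bin, with exact (Clopper–Pearson) 95% binomial intervals. Per-county
uncertainty is the Shannon entropy of the predicted probability,
H = −p·log2 p − (1−p)·log2(1−p), which is 0 at certainty and 1 at p = 0.5.
The per-county residual E = x − p (x the binary record) is a signed
disagreement measure in [−1, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import xlogy
from statsmodels.stats.proportion import proportion_confint

from .metrics import MetricSet, confusion_metrics

__all__ = ["entropy", "residual", "calibration_bins", "evaluate_binary"]

#: decile edges; bins are left-closed right-open, last bin closed
DECILE_EDGES = np.round(np.arange(11) * 0.1, 10)


def entropy(p):
    """Shannon entropy (bits) of a Bernoulli probability, elementwise.

    Uses the 0·log2(0) := 0 convention, so H(0) = H(1) = 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr[~np.isnan(arr)] < 0) | (arr[~np.isnan(arr)] > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / np.log(2.0)
    return h if arr.shape else float(h)


def residual(x, p):
    """Signed residual E = x − p between a binary record and a probability."""
    xa = np.asarray(x, dtype=float)
    pa = np.asarray(p, dtype=float)
    ok = ~np.isnan(xa)
    if np.any((xa[ok] != 0) & (xa[ok] != 1)):
        raise ValueError("records must be binary (0 or 1)")
    if np.any((pa[~np.isnan(pa)] < 0) | (pa[~np.isnan(pa)] > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    e = xa - pa
    return e if e.shape else float(e)


def calibration_bins(
    predictions: pd.Series, labels: pd.DataFrame, subset: str | None = None
) -> pd.DataFrame:
    """Decile reliability table with exact binomial 95% intervals.

    Parameters
    ----------
    predictions
        Calibrated probabilities indexed by county_id.
    labels
        Label table (``county_id``, ``label``, optionally ``split``).
    subset
        Restrict to ``"train"`` or ``"test"``; None uses all labeled counties.

    Returns
    -------
    DataFrame with one row per decile: ``bin_low``, ``bin_high``, ``n``,
    ``k``, ``observed``, ``ci_low``, ``ci_high`` (NaN for empty bins).
    """
    lab = labels
    if subset is not None:
        lab = lab[lab["split"] == subset]
    lab = lab[lab["label"].notna()]
    p = predictions.reindex(lab["county_id"].to_numpy()).to_numpy(dtype=float)
    y = lab["label"].to_numpy(dtype=int)
    keep = ~np.isnan(p)
    p, y = p[keep], y[keep]
    if p.size == 0:
        raise ValueError(f"no labeled counties with predictions in subset {subset!r}")

    # [0,0.1), ..., [0.9,1.0]: p=1 belongs to the last bin
    idx = np.minimum((p / 0.1).astype(int), 9)
    rows = []
    for b in range(10):
        sel = idx == b
        n = int(sel.sum())
        k = int(y[sel].sum())
        if n > 0:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
            obs = k / n
        else:
            lo = hi = obs = np.nan
        rows.append(
            {
                "bin_low": DECILE_EDGES[b],
                "bin_high": DECILE_EDGES[b + 1],
                "n": n,
                "k": k,
                "observed": obs,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def evaluate_binary(
    model_calls: dict[str, pd.Series],
    predictions: pd.Series,
    labels: pd.DataFrame,
    cutoff: float = 0.5,
    subset: str = "test",
    ensemble_name: str = "Ensemble",
) -> pd.DataFrame:
    """Out-of-sample confusion metrics for all base models and the ensemble.

    The ensemble's probabilities are dichotomized at ``cutoff`` (present iff
    p >= cutoff); base-model calls pass through. One row per model, sorted
    by accuracy descending, ties broken alphabetically by model name.
    """
    table: dict[str, MetricSet] = {}
    for name, calls in model_calls.items():
        table[name] = confusion_metrics(calls, labels, subset=subset)
    ens_calls = pd.Series(
        np.where(predictions.isna(), np.nan, (predictions >= cutoff).astype(float)),
        index=predictions.index,
    )
    table[ensemble_name] = confusion_metrics(ens_calls, labels, subset=subset)

    rows = []
    for name, ms in table.items():
        row = {"model_name": name, "subset": subset}
        row.update(ms.as_dict())
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["accuracy", "model_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    cols = [
        "model_name",
        "subset",
        "sensitivity",
        "specificity",
        "ppv",
        "npv",
        "accuracy",
        "tp",
        "fp",
        "tn",
        "fn",
    ]
    return out[cols]
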