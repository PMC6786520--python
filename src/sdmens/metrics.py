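"""Confusion-matrix accuracy metrics on labeled counties.

All metrics are computed only over counties labeled presence or
pseudo-absence; unlabeled counties never enter a confusion matrix. A
metric whose denominator is zero (e.g. PPV with no positive calls) is
reported as ``None`` — never silently as zero — and downstream consumers
must exclude such models explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["MetricSet", "confusion_metrics", "confusion_metrics_arrays"]


@dataclass(frozen=True)
class MetricSet:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics_arrays(calls: np.ndarray, labels: np.ndarray) -> MetricSet:
    """Metrics from aligned binary call and label arrays (no missing values)."""
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must be aligned")
    if calls.size == 0:
        raise ValueError("cannot compute metrics on an empty subset")
    tp = int(np.sum((calls == 1) & (labels == 1)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    return MetricSet(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
    )


def confusion_metrics(
    calls: pd.Series, labels: pd.DataFrame, subset: str | None = None
) -> MetricSet:
    """Confusion metrics of per-county binary ``calls`` against labels.

    Parameters
    ----------
    calls
        Binary calls indexed by county_id (missing calls are dropped with a
        warning).
    labels
        Label table with ``county_id``, ``label`` and, if ``subset`` is
        given, ``split``.
    subset
        ``"train"``, ``"test"`` or ``None`` for all labeled counties.
    """
    lab = labels
    if subset is not None:
        if "split" not in lab.columns:
            raise KeyError("labels have no 'split' column; run split_train_test first")
        lab = lab[lab["split"] == subset]
    lab = lab[lab["label"].notna()]
    merged = lab.set_index("county_id")["label"].astype(int)
    aligned = calls.reindex(merged.index)
    missing = aligned.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} labeled counties have missing calls and are excluded",
            stacklevel=2,
        )
        aligned = aligned[~missing]
        merged = merged[~missing]
    if len(merged) == 0:
        raise ValueError(f"no labeled counties with calls in subset {subset!r}")
    return confusion_metrics_arrays(aligned.to_numpy(dtype=int), merged.to_numpy())
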