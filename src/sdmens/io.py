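"""Readers and writers for the pipeline's CSV/JSON artifacts.

One CSV dialect throughout: comma-separated, UTF-8, header row, county
identifiers kept as zero-padded strings (reading FIPS as integers silently
drops leading zeros — the classic truncation trap). Every file written
here starts with a schema-version header comment which the readers skip.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd

from .records import presence_column

__all__ = [
    "SCHEMA_VERSION",
    "read_county_table",
    "write_county_table",
    "read_labels",
    "write_labels",
    "write_metrics",
    "write_table",
    "read_supplementary_data",
    "write_manifest",
]

SCHEMA_VERSION = "sdmens-schema v1"

_REQUIRED = ("county_id", "name", "lat", "lon", "surveyed")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"county_id": str}, na_values=["NA"])


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame with the schema-version header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, na_rep="NA")


def read_county_table(path, species: tuple[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a county table.

    Requires county_id, name, lat, lon, surveyed and — when ``species`` is
    given — the two ``present_<species>`` columns. Duplicate county ids and
    out-of-range coordinates are errors.
    """
    df = _read_csv(path)
    required = list(_REQUIRED)
    if species is not None:
        required += [presence_column(s) for s in species]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df["county_id"][df["county_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate county_id {dup.iloc[0]!r}")
    bad = df.index[(df["lat"].abs() > 90) | (df["lon"].abs() > 180)]
    if len(bad):
        raise ValueError(f"{path}: coordinates out of range at row {int(bad[0])}")
    return df


def write_county_table(df: pd.DataFrame, path) -> None:
    write_table(df, path)


def read_labels(path) -> pd.DataFrame:
    df = _read_csv(path)
    df["label"] = df["label"].astype("Int64")
    return df


def write_labels(labels: pd.DataFrame, path) -> None:
    write_table(labels, path)


def write_metrics(metrics: pd.DataFrame, path) -> None:
    write_table(metrics, path)


def read_supplementary_data(
    path,
    model_columns: list[str],
    label_column: str = "label",
    split_column: str = "split",
    prob_column: str | None = None,
):
    """Read a published per-county dataset in the supplementary-data layout.

    Expected columns: ``fips`` (or ``county_id``), ``name``, ``lat``/
    ``latitude``, ``lon``/``longitude``, a presence(1)/pseudo-absence(0)
    label with train/test assignment, one binary column per base model,
    and optionally the published calibrated ensemble probability.

    Returns ``(labels, calls, published_prob)`` — a label table with
    county_id/label/split, a counties x models call DataFrame, and the
    published probability Series (or None).
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    rename = {}
    for cand, target in (
        ("fips", "county_id"),
        ("latitude", "lat"),
        ("longitude", "lon"),
    ):
        if cand in df.columns and target not in df.columns:
            rename[cand] = target
    df = df.rename(columns=rename)
    if "county_id" not in df.columns:
        raise ValueError(f"{path}: no county identifier column (fips/county_id)")
    df["county_id"] = df["county_id"].str.zfill(5)
    for col in (label_column, split_column, *model_columns):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    labels = pd.DataFrame(
        {
            "county_id": df["county_id"],
            "label": pd.array(pd.to_numeric(df[label_column], errors="coerce"), dtype="Int64"),
            "split": df[split_column].fillna("none"),
        }
    )
    calls = pd.DataFrame(
        {m: pd.to_numeric(df[m], errors="coerce") for m in model_columns}
    )
    calls.index = df["county_id"].to_numpy()
    prob = None
    if prob_column is not None:
        prob = pd.Series(
            pd.to_numeric(df[prob_column], errors="coerce").to_numpy(),
            index=df["county_id"].to_numpy(),
        )
    return labels, calls, prob


def write_manifest(path, config: dict, seed: int) -> None:
    """Record the run configuration, seed and library versions."""
    import numpy, pandas, scipy, sklearn, statsmodels

    from . import __version__

    payload = {
        "schema": SCHEMA_VERSION,
        "config": config,
        "seed": seed,
        "python": sys.version.split()[0],
        "versions": {
            "sdmens": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str))
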