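"""Presence / pseudo-absence labeling of county records.

A county is "present" for a species if at least one mosquito of any life
stage was collected and reported there. Counties without a report are not
treated as absences wholesale; a county is labeled *pseudo-absent* for
species A only when all three of the following hold:

1. no local report of species A;
2. evidence of detection effort — the county conducts mosquito
   surveillance, or the co-surveyed species B was reported there;
3. the county centroid is at least ``buffer_km`` (default 100 km) from the
   centroid of the nearest county with a species-A report.

Counties failing condition 2 or falling inside the buffer stay unlabeled
and are excluded from training and evaluation. Setting ``buffer_km=0``
recovers the unbuffered variant.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "pairwise_haversine_km",
    "classify_pseudo_absence",
    "split_train_test",
    "presence_column",
]

EARTH_RADIUS_KM = 6371.0

LABEL_PRESENCE = 1
LABEL_PSEUDO_ABSENCE = 0


def presence_column(species: str) -> str:
    """Column name holding the observed presence flag for ``species``."""
    return f"present_{species}"


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of range: lat must be in [-90, 90], lon in [-180, 180]")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) pairs in degrees."""
    lat1, lon1 = a
    lat2, lon2 = b
    _check_coords(np.array([lat1, lat2]), np.array([lon1, lon2]))
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Distance matrix (len(lat1) x len(lat2)) of great-circle distances in km."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1 = np.radians(np.asarray(lat1, dtype=float))[:, None]
    phi2 = np.radians(np.asarray(lat2, dtype=float))[None, :]
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float))[None, :] - np.radians(
        np.asarray(lon1, dtype=float)
    )[:, None]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def classify_pseudo_absence(
    counties: pd.DataFrame,
    species: str,
    other_species: str,
    buffer_km: float = 100.0,
) -> pd.DataFrame:
    """Label every county as presence (1), pseudo-absence (0) or unlabeled.

    Parameters
    ----------
    counties
        County table with columns ``county_id``, ``lat``, ``lon``,
        ``present_<species>``, ``present_<other_species>``, ``surveyed``.
    species, other_species
        Identifiers of the target species and the co-surveyed species.
    buffer_km
        Exclusion radius around presence centroids. A candidate county is
        excluded (left unlabeled) iff its distance to the nearest presence
        centroid is strictly less than ``buffer_km``; "at least" the radius
        qualifies.

    Returns
    -------
    DataFrame with columns ``county_id``, ``species``, ``label`` (nullable
    Int64: 1, 0 or <NA>).
    """
    col_a = presence_column(species)
    col_b = presence_column(other_species)
    for col in ("county_id", "lat", "lon", col_a, col_b, "surveyed"):
        if col not in counties.columns:
            raise KeyError(f"county table is missing required column {col!r}")
    if buffer_km < 0:
        raise ValueError("buffer_km must be non-negative")

    present = counties[col_a].to_numpy(dtype=bool)
    other = counties[col_b].to_numpy(dtype=bool)
    surveyed = counties["surveyed"].to_numpy(dtype=bool)
    lat = counties["lat"].to_numpy(dtype=float)
    lon = counties["lon"].to_numpy(dtype=float)

    label = np.full(len(counties), pd.NA, dtype=object)
    label[present] = LABEL_PRESENCE

    candidate = (~present) & (surveyed | other)
    if candidate.any():
        if present.any() and buffer_km > 0:
            dist = pairwise_haversine_km(
                lat[candidate], lon[candidate], lat[present], lon[present]
            )
            far_enough = dist.min(axis=1) >= buffer_km
        else:
            far_enough = np.ones(int(candidate.sum()), dtype=bool)
        idx = np.flatnonzero(candidate)[far_enough]
        label[idx] = LABEL_PSEUDO_ABSENCE

    return pd.DataFrame(
        {
            "county_id": counties["county_id"].to_numpy(),
            "species": species,
            "label": pd.array(label, dtype="Int64"),
        }
    )


def split_train_test(
    labels: pd.DataFrame, fraction: float = 0.8, seed: int = 0
) -> pd.DataFrame:
    """Assign labeled counties to train/test, stratified by class.

    Within each class independently, round-half-up(fraction * n_class)
    counties go to the training set and the remainder to the test set;
    unlabeled counties get split ``"none"``. 291 presence counties at the
    default fraction therefore yield 233 train / 58 test.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    out = labels.copy()
    split = np.full(len(out), "none", dtype=object)
    lab = out["label"]
    for cls in (LABEL_PRESENCE, LABEL_PSEUDO_ABSENCE):
        idx = np.flatnonzero((lab == cls).fillna(False).to_numpy())
        if idx.size == 0:
            continue
        n_train = int(math.floor(fraction * idx.size + 0.5))  # round half up
        perm = rng.permutation(idx.size)
        split[idx[perm[:n_train]]] = "train"
        split[idx[perm[n_train:]]] = "test"
    out["split"] = split
    return out
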