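"""Synthetic county data with known ground truth.

Generates a regular lon/lat county lattice, a spatially autocorrelated
true presence-probability surface per species, stochastic surveillance
and detection, and base suitability models with designed sensitivity and
specificity, so every downstream stage (labeling, dichotomization,
ensembling, calibration, evaluation) can be validated against ground
truth.

The latent occupancy field is kernel-smoothed white noise on the lattice
(a cheap stand-in for an exact Gaussian process with controllable
correlation length), pushed through a logistic transform whose intercept
is root-found so that the mean presence probability hits the configured
prevalence. Observed presence requires occupancy, surveillance in the
county, and a Bernoulli detection success.

Randomness: a single master seed; each component (field per species,
occupancy, surveillance, detection, each base model) draws from its own
stream spawned as ``SeedSequence((seed, stream_offset))`` with fixed,
documented offsets, so adding a component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit, logit

from .records import presence_column

__all__ = ["SyntheticConfig", "generate_counties", "generate_truth", "simulate_base_model", "simulate_dataset"]

# fixed per-component stream offsets (see module docstring)
_STREAM_FIELD_A = 0
_STREAM_FIELD_B = 1
_STREAM_OCCUPANCY = 2
_STREAM_SURVEILLANCE = 3
_STREAM_DETECTION = 4
_STREAM_MODELS = 100  # model j for species s uses offset 100 + 2*j + s

#: slope applied to the unit-variance latent field inside the logistic
LATENT_SLOPE = 2.0


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic county world."""

    n_rows: int = 50
    n_cols: int = 60
    lat_origin: float = 30.0
    lon_origin: float = -100.0
    cell_deg: float = 1.0
    smoothness: float = 3.0
    mean_prevalence: float = 0.3
    surveillance_fraction: float = 0.6
    detection_prob: float = 0.9
    species: tuple[str, str] = ("speciesA", "speciesB")
    species_correlation: float = 0.0
    model_specs: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.85, 0.80), (0.75, 0.90), (0.90, 0.70), (0.65, 0.95), (0.80, 0.85)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 4:
            raise ValueError("lattice must have at least 4 counties")
        if self.cell_deg <= 0 or self.smoothness <= 0:
            raise ValueError("cell_deg and smoothness must be positive")
        if not (0.0 < self.mean_prevalence < 1.0):
            raise ValueError("mean_prevalence must lie in (0, 1)")
        if not (0.0 <= self.surveillance_fraction <= 1.0):
            raise ValueError("surveillance_fraction must lie in [0, 1]")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must lie in (0, 1]")
        if not (-1.0 <= self.species_correlation <= 1.0):
            raise ValueError("species_correlation must lie in [-1, 1]")
        if not self.model_specs:
            raise ValueError("model_specs must be non-empty")
        for se, sp in self.model_specs:
            if not (0.0 < se <= 1.0 and 0.0 < sp <= 1.0):
                raise ValueError("sensitivity and specificity must lie in (0, 1]")
        if len(self.species) != 2 or self.species[0] == self.species[1]:
            raise ValueError("exactly two distinct species identifiers are required")


def _rng(config_seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config_seed, offset)))


def generate_counties(config: SyntheticConfig) -> pd.DataFrame:
    """Regular lon/lat lattice of counties with unique FIPS-like ids.

    Row r, column c sits at (lat_origin + r*cell_deg, lon_origin + c*cell_deg);
    ids are zero-padded in row-major order.
    """
    r, c = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij")
    r, c = r.ravel(), c.ravel()
    n = r.size
    return pd.DataFrame(
        {
            "county_id": [f"{i:05d}" for i in range(n)],
            "name": [f"County-{ri}-{ci}" for ri, ci in zip(r, c)],
            "lat": config.lat_origin + r * config.cell_deg,
            "lon": config.lon_origin + c * config.cell_deg,
            "row": r,
            "col": c,
        }
    )


def _latent_field(config: SyntheticConfig, offset: int) -> np.ndarray:
    """Unit-variance kernel-smoothed white-noise field, row-major raveled."""
    rng = _rng(config.seed, offset)
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    z = gaussian_filter(noise, sigma=config.smoothness, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z.ravel()


def _target_intercept(z: np.ndarray, prevalence: float) -> float:
    """Intercept b with mean(expit(b + slope*z)) = prevalence, to 1e-3."""

    def gap(b: float) -> float:
        return float(expit(b + LATENT_SLOPE * z).mean() - prevalence)

    lo, hi = logit(prevalence) - 10.0, logit(prevalence) + 10.0
    return brentq(gap, lo, hi, xtol=1e-6)


def generate_truth(counties: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """True presence probabilities, occupancy, surveillance and observations.

    Returns one row per county with, per species s: ``true_prob_<s>``
    (spatially autocorrelated, mean ≈ mean_prevalence), ``true_present_<s>``
    (Bernoulli occupancy) and ``present_<s>`` (observed: occupied,
    surveyed, and detected with probability detection_prob), plus the
    shared ``surveyed`` flag.
    """
    n = len(counties)
    z_a = _latent_field(config, _STREAM_FIELD_A)
    z_b_raw = _latent_field(config, _STREAM_FIELD_B)
    rho = config.species_correlation
    z_b = rho * z_a + np.sqrt(1.0 - rho**2) * z_b_raw

    occ_rng = _rng(config.seed, _STREAM_OCCUPANCY)
    surv_rng = _rng(config.seed, _STREAM_SURVEILLANCE)
    det_rng = _rng(config.seed, _STREAM_DETECTION)

    surveyed = (surv_rng.random(n) < config.surveillance_fraction).astype(int)
    out = counties[["county_id"]].copy()
    out["surveyed"] = surveyed
    for sp, z in zip(config.species, (z_a, z_b)):
        b = _target_intercept(z, config.mean_prevalence)
        prob = expit(b + LATENT_SLOPE * z)
        occupied = (occ_rng.random(n) < prob).astype(int)
        detected = (det_rng.random(n) < config.detection_prob).astype(int)
        out[f"true_prob_{sp}"] = prob
        out[f"true_present_{sp}"] = occupied
        out[presence_column(sp)] = occupied * surveyed * detected
    return out


def simulate_base_model(
    truth: pd.DataFrame,
    sensitivity: float,
    specificity: float,
    seed,
    species: str | None = None,
) -> pd.Series:
    """Binary base-model calls with designed operating characteristics.

    Truly occupied counties are called present with probability
    ``sensitivity``; truly unoccupied counties are called absent with
    probability ``specificity``. ``seed`` may be an int or a SeedSequence.
    """
    if not (0.0 < sensitivity <= 1.0 and 0.0 < specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in (0, 1]")
    col = f"true_present_{species}" if species is not None else None
    if col is None:
        candidates = [c for c in truth.columns if c.startswith("true_present_")]
        if len(candidates) != 1:
            raise ValueError("species must be given when truth covers several species")
        col = candidates[0]
    occupied = truth[col].to_numpy(dtype=bool)
    rng = np.random.default_rng(seed)
    u = rng.random(occupied.size)
    calls = np.where(occupied, (u < sensitivity).astype(float), (u < 1.0 - specificity).astype(float))
    return pd.Series(calls, index=truth["county_id"].to_numpy(), name="call")


def simulate_dataset(config: SyntheticConfig):
    """End-to-end synthetic inputs for the pipeline.

    Returns ``(counties, truth, calls)`` where ``counties`` is the observed
    county table (centroids, observed presence per species, surveillance),
    ``truth`` holds the generating probabilities and occupancy, and
    ``calls`` maps each species to a counties x models DataFrame of binary
    base-model calls.
    """
    counties = generate_counties(config)
    truth = generate_truth(counties, config)
    observed = counties.merge(
        truth[
            ["county_id", "surveyed"]
            + [presence_column(sp) for sp in config.species]
        ],
        on="county_id",
    )
    calls: dict[str, pd.DataFrame] = {}
    for s_idx, sp in enumerate(config.species):
        cols = {}
        for j, (se, spc) in enumerate(config.model_specs):
            stream = np.random.SeedSequence(
                (config.seed, _STREAM_MODELS + 2 * j + s_idx)
            )
            cols[f"model_{j}"] = simulate_base_model(truth, se, spc, stream, species=sp)
        calls[sp] = pd.DataFrame(cols)
    return observed, truth, calls
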