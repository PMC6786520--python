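"""End-to-end orchestration: label -> split -> dichotomize -> ensemble -> evaluate."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .base_models import BaseModelPrediction, dichotomize
from .ensemble import AccuracyWeightedEnsemble
from .evaluation import calibration_bins, entropy, evaluate_binary, residual
from .records import classify_pseudo_absence, split_train_test

logger = logging.getLogger("sdmens")

__all__ = ["PipelineConfig", "SpeciesResult", "run_species", "run_pipeline"]


@dataclass
class PipelineConfig:
    species: tuple[str, str] = ("speciesA", "speciesB")
    buffer_km: float = 100.0
    split_fraction: float = 0.8
    seed: int = 0
    cutoff_step: float = 0.01
    ensemble_cutoff: float = 0.5
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.buffer_km < 0:
            raise ValueError("buffer_km must be non-negative")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if not (0.0 < self.cutoff_step <= 0.5):
            raise ValueError("cutoff_step must lie in (0, 0.5]")
        if not (0.0 <= self.ensemble_cutoff <= 1.0):
            raise ValueError("ensemble_cutoff must lie in [0, 1]")


@dataclass
class SpeciesResult:
    """All artifacts of one species' analysis."""

    species: str
    labels: pd.DataFrame
    models: list[BaseModelPrediction]
    ensemble: AccuracyWeightedEnsemble
    predictions: pd.Series  # calibrated p per county
    county_report: pd.DataFrame  # county_id, raw_score, p, H, E, label, split
    train_metrics: pd.DataFrame
    test_metrics: pd.DataFrame
    bins_train: pd.DataFrame
    bins_test: pd.DataFrame


def _metrics_frame(models: list[BaseModelPrediction], subset: str) -> pd.DataFrame:
    rows = []
    for m in models:
        row = {"model_name": m.model_name, "subset": subset}
        row.update(m.training_metrics.as_dict())
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        by=["accuracy", "model_name"], ascending=[False, True], kind="mergesort"
    )
    cols = ["model_name", "subset", "sensitivity", "specificity", "ppv", "npv",
            "accuracy", "tp", "fp", "tn", "fn"]
    return out[cols].reset_index(drop=True)


def run_species(
    counties: pd.DataFrame,
    models: list[BaseModelPrediction],
    species: str,
    other_species: str,
    config: PipelineConfig,
) -> SpeciesResult:
    """Run the full procedure for one species."""
    labels = classify_pseudo_absence(
        counties, species, other_species, buffer_km=config.buffer_km
    )
    labels = split_train_test(labels, fraction=config.split_fraction, seed=config.seed)
    n_pres = int((labels["label"] == 1).sum())
    n_abs = int((labels["label"] == 0).sum())
    logger.info(
        "%s: %d presence, %d pseudo-absence, %d unlabeled counties",
        species, n_pres, n_abs, len(labels) - n_pres - n_abs,
    )

    fitted = [dichotomize(m, labels, step=config.cutoff_step) for m in models]
    train_metrics = _metrics_frame(fitted, "train")

    calls = pd.DataFrame({m.model_name: m.binary_call for m in fitted})
    train = labels[(labels["split"] == "train") & labels["label"].notna()]
    X_train = calls.reindex(train["county_id"].to_numpy())
    y_train = train["label"].to_numpy(dtype=int)
    ens = AccuracyWeightedEnsemble(threshold=config.ensemble_cutoff)
    ens.fit(X_train, y_train)
    logger.info("%s: calibration edf %.2f", species, ens.edf_)

    raw_all = pd.Series(ens.raw_score(calls), index=calls.index, name="raw_score")
    p_all = pd.Series(ens.predict_proba(calls)[:, 1], index=calls.index, name="p")

    model_calls = {m.model_name: m.binary_call for m in fitted}
    test_metrics = evaluate_binary(
        model_calls, p_all, labels, cutoff=config.ensemble_cutoff, subset="test"
    )
    bins_train = calibration_bins(p_all, labels, subset="train")
    bins_test = calibration_bins(p_all, labels, subset="test")

    lab_idx = labels.set_index("county_id")
    report = pd.DataFrame(
        {
            "county_id": calls.index,
            "raw_score": raw_all.to_numpy(),
            "p": p_all.to_numpy(),
            "H": entropy(p_all.to_numpy()),
        }
    )
    report["label"] = lab_idx["label"].reindex(report["county_id"]).to_numpy()
    report["split"] = lab_idx["split"].reindex(report["county_id"]).to_numpy()
    x = report["label"].astype(float).to_numpy()
    report["E"] = np.where(np.isnan(x), np.nan, x - report["p"].to_numpy())
    return SpeciesResult(
        species=species,
        labels=labels,
        models=fitted,
        ensemble=ens,
        predictions=p_all,
        county_report=report,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        bins_train=bins_train,
        bins_test=bins_test,
    )


def run_pipeline(
    counties: pd.DataFrame,
    models: dict[str, list[BaseModelPrediction]],
    config: PipelineConfig,
) -> dict[str, SpeciesResult]:
    """Run both species and, if configured, write every artifact to disk.

    ``models`` maps each species to its list of base models. Outputs per
    species: labels, per-model cutoff sidecars, train/test metrics tables,
    calibration bins, and the per-county report (raw score, calibrated p,
    entropy H, residual E).
    """
    sp_a, sp_b = config.species
    results: dict[str, SpeciesResult] = {}
    for species, other in ((sp_a, sp_b), (sp_b, sp_a)):
        results[species] = run_species(
            counties, models.get(species, []), species, other, config
        )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_manifest(out / "manifest.json", asdict(config), config.seed)
        for species, res in results.items():
            d = out / species
            sio.write_labels(res.labels, d / "labels.csv")
            sio.write_metrics(res.train_metrics, d / "train_metrics.csv")
            sio.write_metrics(res.test_metrics, d / "test_metrics.csv")
            sio.write_table(res.bins_train, d / "calibration_bins_train.csv")
            sio.write_table(res.bins_test, d / "calibration_bins_test.csv")
            sio.write_table(res.county_report, d / "county_report.csv")
            (d / "ensemble.json").write_text(res.ensemble.to_json())
            cut = {
                m.model_name: {"kind": m.kind, "cutoff": m.cutoff}
                for m in res.models
            }
            import json

            (d / "cutoffs.json").write_text(json.dumps(cut, indent=2))
    return results
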