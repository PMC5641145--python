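"""End-to-end workflow: simulate (or load) -> extract -> select -> score -> evaluate.

Every run writes its artifacts plus a manifest (serialized config, package
version, seed) into the output directory, so a run can be reproduced from
its own outputs.  All randomness fans out from the single configured seed
via named substreams (cohort generation, fold assignment, bootstrap), so a
rerun with the same config reproduces every non-stochastic artifact
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import apply_labels, evaluate_models, group_difference_tests, roc_curve_points
from .features import extract_patient
from .io import read_feature_table, read_mask, read_volume, write_feature_table
from .model import RadScoreModel, score_table
from .synthetic import ClassEffect, SyntheticCohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

_SUBSTREAMS = {"cohort": 0, "folds": 1, "bootstrap": 2}


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the single pipeline seed."""
    child = np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],))
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    output_dir: str = "radsig_run"
    input_dir: str | None = None  # None => synthetic mode
    seed: int = 0
    # extraction
    n_bins: int = 32
    wavelet: str = "coif1"
    # selection
    folds: int = 10
    lambda_rule: str = "min"
    # evaluation
    cutoff_months: float = 36.0
    ci_method: str = "delong"
    censored: str = "exclude"
    # synthetic cohort (used only when input_dir is None)
    n_train: int = 80
    n_val: int = 33
    prevalence: float = 0.3
    grid_shape: tuple[int, int, int] = (44, 44, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    tumor_radius_range: tuple[float, float] = (14.0, 18.0)
    mean_shift: float = 10.0
    corr_length_mm: tuple[float, float] = (2.0, 3.5)
    noise_sd: float = 10.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def synthetic_config(self) -> SyntheticCohortConfig:
        return SyntheticCohortConfig(
            n_train=self.n_train,
            n_val=self.n_val,
            prevalence=self.prevalence,
            grid_shape=tuple(self.grid_shape),
            voxel_spacing=tuple(self.voxel_spacing),
            tumor_radius_range=tuple(self.tumor_radius_range),
            class_effect=ClassEffect(self.mean_shift, tuple(self.corr_length_mm), self.noise_sd),
            seed=substream_seed(self.seed, "cohort"),
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            out = fn(*args, **kwargs)
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("simulate")
def simulate_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    patients, clinical = generate_cohort(config.synthetic_config())
    table = write_cohort(patients, clinical, outdir / "images")
    return table


@_stage("extract")
def extract_stage(config: PipelineConfig, cohort: pd.DataFrame, image_dir: Path) -> pd.DataFrame:
    records = []
    for row in cohort.itertuples():
        try:
            cet1 = read_volume(image_dir / row.cet1_path, "CET1-w")
            t2 = read_volume(image_dir / row.t2_path, "T2-w")
            mask_c = read_mask(image_dir / row.mask_path, cet1)
            mask_t = read_mask(image_dir / row.mask_path, t2)
            feats = extract_patient(
                (cet1, mask_c), (t2, mask_t), n_bins=config.n_bins, wavelet=config.wavelet
            )
        except Exception as exc:
            raise RuntimeError(f"stage extract failed for patient {row.id}: {exc}") from exc
        records.append((row.id, feats))
    out = Path(config.output_dir) / "feature_table.csv"
    return write_feature_table(records, out)


@_stage("evaluate")
def evaluate_stage(
    config: PipelineConfig, features: pd.DataFrame, clinical: pd.DataFrame
) -> dict:
    labeled = clinical.copy()
    if "progressed" not in labeled.columns:
        # synthetic cohorts: the planted label is the event indicator
        labeled["progressed"] = labeled["label"].astype(bool)
    labeled = apply_labels(labeled, config.cutoff_months, config.censored)
    labeled = labeled.set_index("id")
    train_ids = labeled.index[labeled["cohort"] == "training"]
    val_ids = labeled.index[labeled["cohort"] == "validation"]
    x_tr, y_tr = features.loc[train_ids], labeled.loc[train_ids, "label"].values
    x_va, y_va = features.loc[val_ids], labeled.loc[val_ids, "label"].values
    results = evaluate_models(
        x_tr,
        y_tr,
        x_va,
        y_va,
        folds=config.folds,
        seed=substream_seed(config.seed, "folds"),
        ci_method=config.ci_method,
    )
    outdir = Path(config.output_dir)
    metrics: dict = {"models": {}}
    for name, res in results.items():
        metrics["models"][name] = {
            "selected": res["selected"],
            "n_selected": len(res["selected"]),
            **{
                cohort: {
                    "auc": res[cohort].auc,
                    "ci": [res[cohort].ci_low, res[cohort].ci_high],
                    "n_pos": res[cohort].n_pos,
                    "n_neg": res[cohort].n_neg,
                }
                for cohort in ("training", "validation")
            },
        }
        (outdir / f"model_{name}.json").write_text(res["model"].to_json())
    combined = results["combined"]
    scores = score_table(combined["model"], features)
    scores.to_frame().to_csv(outdir / "rad_scores.csv")
    roc_curve_points(
        scores.loc[val_ids].values, y_va
    ).to_csv(outdir / "roc_validation_combined.csv", index=False)
    tests = group_difference_tests(x_tr[combined["selected"]], y_tr) if combined["selected"] else None
    if tests is not None:
        tests.to_csv(outdir / "selected_feature_tests.csv", index=False)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the metrics dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "radsig",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.to_json()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    from .names import feature_dictionary

    (outdir / "feature_dictionary.json").write_text(json.dumps(feature_dictionary(), indent=2))

    if config.input_dir is None:
        cohort = simulate_stage(config, outdir)
        image_dir = outdir / "images"
    else:
        image_dir = Path(config.input_dir)
        cohort_csv = image_dir / "cohort.csv"
        if not cohort_csv.exists():
            raise FileNotFoundError(f"stage load: missing cohort table {cohort_csv}")
        cohort = pd.read_csv(cohort_csv)

    features = extract_stage(config, cohort, image_dir)
    metrics = evaluate_stage(config, features, cohort)
    return metrics


def score_command(model_json, feature_table, output_csv) -> pd.DataFrame:
    """Append a rad_score column to a feature table; the input is untouched."""
    model = RadScoreModel.from_json(Path(model_json).read_text())
    table = read_feature_table(feature_table)
    scored = table.copy()
    scored["rad_score"] = score_table(model, table) if len(table) else pd.Series(dtype=float)
    scored.to_csv(output_csv, float_format="%.12g")
    return scored
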