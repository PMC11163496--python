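"""End-to-end experiment glue: cohort -> doses -> map stacks -> training.

The measured arm of each beam is always the *error-free* plan (that is what
a QA session delivers); the predicted arm is rendered per manifest row with
the row's error injected.  Class labels are the five error families in the
fixed order shift, random, error_free, opening, closing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from qaerr.dose import EngineParams, beam_dose, measure, synthesize_cohort
from qaerr.errors import apply_error, build_manifest, spec_from_row
from qaerr.maps import CHANNEL_NAMES, MapStack, make_stack
from qaerr.metrics import MetricsReport, compute_metrics
from qaerr.network import NetConfig, desk_config
from qaerr.plans import Beam, ERROR_FAMILIES
from qaerr.training import (
    TrainConfig,
    desk_train_config,
    ensemble_predict,
    kfold_by_plan,
    split_plan_level,
    train_fold,
)

log = logging.getLogger(__name__)


@dataclass
class StackDataset:
    """In-memory dataset of map stacks aligned with a manifest."""

    images: np.ndarray            # (N, size, size, 3) float32, NHWC
    labels: np.ndarray            # (N,) int indices into ERROR_FAMILIES
    manifest: pd.DataFrame        # N rows, aligned

    def nchw(self, channels: str = "all") -> np.ndarray:
        """NCHW view, optionally restricted to one channel for ablations."""
        x = self.images.transpose(0, 3, 1, 2)
        if channels == "all":
            return x
        idx = CHANNEL_NAMES.index(channels)
        return x[:, idx:idx + 1]

    def subset(self, rows: pd.DataFrame) -> "StackDataset":
        idx = rows.index.to_numpy()
        return StackDataset(self.images[idx], self.labels[idx],
                            rows.reset_index(drop=True))


def generate_dataset(beams: list[Beam], manifest: pd.DataFrame,
                     engine: EngineParams, size: int = 96) -> StackDataset:
    """Render every manifest row into a map stack.

    One measured (noisy, error-free) dose per beam; one predicted dose per
    manifest row with that row's error injected into the prediction arm.
    """
    by_beam = {(b.plan_id, b.beam_id): b for b in beams}
    images = np.zeros((len(manifest), size, size, 3), dtype=np.float32)
    labels = np.zeros(len(manifest), dtype=np.int64)

    measured_cache: dict[tuple[str, str], object] = {}
    free_cache: dict[tuple[str, str], object] = {}
    for bi, key in enumerate(sorted(by_beam)):
        beam = by_beam[key]
        free = beam_dose(beam, engine)
        free_cache[key] = free
        noise_params = EngineParams(
            penumbra_sigma_mm=engine.penumbra_sigma_mm,
            transmission=engine.transmission,
            noise_sd_fraction=engine.noise_sd_fraction,
            seed=engine.seed * 100_003 + bi,
        )
        measured_cache[key] = measure(free, noise_params)

    manifest = manifest.reset_index(drop=True)
    for i, row in manifest.iterrows():
        key = (row["plan_id"], row["beam_id"])
        beam = by_beam[key]
        spec = spec_from_row(row)
        predicted = (free_cache[key] if spec.family == "error_free"
                     else beam_dose(apply_error(beam, spec), engine))
        stack = make_stack(predicted, measured_cache[key], label=spec.family,
                           plan_id=key[0], beam_id=key[1], size=size)
        images[i] = stack.channels
        labels[i] = ERROR_FAMILIES.index(spec.family)
    return StackDataset(images, labels, manifest)


@dataclass
class ExperimentResult:
    report: MetricsReport
    fold_reports: list[MetricsReport]
    histories: list
    test_probabilities: np.ndarray
    test_labels: np.ndarray
    models: list


def run_experiment(dataset: StackDataset, net_config: NetConfig,
                   train_config: TrainConfig,
                   channels: str = "all") -> ExperimentResult:
    """Plan-level split, k-fold training, ensemble-mean test evaluation."""
    manifest = dataset.manifest.reset_index(drop=True)
    train_rows, test_rows = split_plan_level(
        manifest, train_config.test_fraction, train_config.seed)
    folds = kfold_by_plan(train_rows, train_config.folds, train_config.seed)

    test = dataset.subset(test_rows)
    test_x = test.nchw(channels)

    models, histories, fold_reports = [], [], []
    for fi, (ftrain, fval) in enumerate(folds):
        tr = dataset.subset(ftrain)
        va = dataset.subset(fval)
        cfg = TrainConfig(
            lr=train_config.lr, weight_decay=train_config.weight_decay,
            batch_size=train_config.batch_size,
            max_epochs=train_config.max_epochs,
            patience=train_config.patience, folds=train_config.folds,
            test_fraction=train_config.test_fraction,
            augment=train_config.augment,
            seed=train_config.seed * 97 + fi,
        )
        model, hist = train_fold(tr.nchw(channels), tr.labels,
                                 va.nchw(channels), va.labels,
                                 net_config, cfg)
        models.append(model)
        histories.append(hist)
        fold_reports.append(compute_metrics(
            model.predict_proba(test_x), test.labels))
        log.info("fold %d: best epoch %d, test accuracy %.3f", fi,
                 hist.best_epoch, fold_reports[-1].macro["accuracy"])

    probs = ensemble_predict(models, test_x)
    report = compute_metrics(probs, test.labels)
    return ExperimentResult(report, fold_reports, histories, probs,
                            test.labels, models)


def desk_cohort(n_plans: int = 20, beams_per_plan: int = 3,
                seed: int = 0) -> tuple[list[Beam], pd.DataFrame]:
    """The reduced-scale study cohort: 20 plans x 3 beams by default."""
    beams = synthesize_cohort(n_plans, beams_per_plan, seed=seed)
    manifest = build_manifest(beams, base_seed=seed)
    return beams, manifest


def run_desk_experiment(seed: int = 0, n_plans: int = 20,
                        beams_per_plan: int = 3, channels: str = "all",
                        engine: EngineParams | None = None) -> ExperimentResult:
    """Full scaled-down pipeline at the desk profile (96x96, slim net)."""
    engine = engine or EngineParams(seed=seed)
    beams, manifest = desk_cohort(n_plans, beams_per_plan, seed)
    dataset = generate_dataset(beams, manifest, engine, size=96)
    in_ch = 3 if channels == "all" else 1
    return run_experiment(dataset, desk_config(in_channels=in_ch, seed=seed),
                          desk_train_config(seed), channels)
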