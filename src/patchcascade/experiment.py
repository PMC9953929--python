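"""Training contracts and the repeated-repetition experiment runner.

The protocol compared here: for each repetition, subjects are re-split
70/10/20 with class proportions preserved, the test set is balanced by
matched undersampling, and every condition (a patch-partition scheme, or
the whole-volume baseline) is trained and evaluated on the *same* splits —
a paired design, which is what makes the repeated-measures ANOVA across
conditions valid. Repetitions re-randomize splits, undersampling, and
network initialization. Accuracy per repetition × condition feeds the
ANOVA with Greenhouse–Geisser correction and Tukey post hoc pairs.

Two size profiles exist: the full-size profile mirrors the study design
exactly (91×115×91 volumes, channels 8/16/32/64, 300/200 epochs, 20
repetitions); the desk profile shrinks volumes, patch shapes, channel
widths and epoch caps proportionally so a full multi-condition experiment
runs in minutes on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import baseline_spec
from .cohort import CohortConfig, SubjectRecord, generate_cohort_arrays
from .estimators import CNNClassifier, CascadeClassifier
from .evaluation import (
    SplitConfig,
    compute_metrics,
    rm_anova,
    stratified_split,
    tukey_posthoc,
    undersample_match,
)
from .patches import PatchSpec, plan_grid, roi_patch_specs
from .volume import Volume

__all__ = [
    "TrainConfig",
    "Condition",
    "ExperimentConfig",
    "train_model",
    "train_cascade",
    "grid_search",
    "run_experiment",
    "desk_cohort_config",
    "desk_train_config",
    "desk_conditions",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule hyperparameters (Adam throughout).

    Defaults are the full-size profile: learning rate 1e-4, batch 24,
    dropout 0.5, 300 epochs for subject-level training and 200 for
    patch-level subnetworks (they converge faster), early stopping with
    patience 20 on the validation loss.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 24
    dropout: float = 0.5
    max_epochs: int = 300
    patch_max_epochs: int = 200
    early_stop_patience: int = 20
    l2: float = 1e-4
    monitor: str = "val_loss"  # or "val_acc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.max_epochs < self.early_stop_patience:
            raise ValueError("max_epochs must be >= patience")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass(frozen=True)
class Condition:
    """One experimental arm: a partition method with its patch layout.

    ``method``: 'grid' (regular overlapping grid), 'roi' (patches centered
    on configured coordinates), or 'baseline' (whole volume, no patches).
    """

    name: str
    method: str = "grid"
    patch_shape: tuple[int, int, int] | None = None
    counts: tuple[int, int, int] | None = None
    centers: tuple[tuple[int, int, int], ...] | None = None
    channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    subnet_fc_units: tuple[int, int] = (1024, 128)
    fusion_fc_units: tuple[int, int] = (2048, 512)

    def patch_specs(self, volume_shape: Sequence[int]) -> tuple[PatchSpec, ...]:
        if self.method == "grid":
            plan = plan_grid(volume_shape, self.patch_shape, self.counts)
            return plan.specs
        if self.method == "roi":
            return tuple(roi_patch_specs(self.centers, self.patch_shape, volume_shape))
        if self.method == "baseline":
            return ()
        raise ValueError(f"unknown partition method {self.method!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """The full repeated experiment: cohort, conditions, repetitions."""

    cohort: CohortConfig
    conditions: tuple[Condition, ...]
    n_repetitions: int = 20
    half_training: bool = False
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


def _repetition_seed(global_seed: int, repetition: int) -> int:
    return int(
        np.random.SeedSequence((global_seed, repetition)).generate_state(1)[0] % (2**31)
    )


def train_model(
    spec, X, y, X_val, y_val, cfg: TrainConfig
) -> CNNClassifier:
    """Train a single network on volumes; returns the fitted classifier."""
    clf = CNNClassifier(
        spec=spec,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.early_stop_patience,
        dropout=cfg.dropout,
        l2=cfg.l2,
        monitor=cfg.monitor,
        random_state=cfg.seed,
    )
    return clf.fit(X, y, X_val=X_val, y_val=y_val)


def train_cascade(
    patch_specs: Sequence[PatchSpec],
    X,
    y,
    X_val,
    y_val,
    cfg: TrainConfig,
    condition: Condition | None = None,
) -> CascadeClassifier:
    """Train the two-stage cascade for a patch plan; returns the fitted model."""
    cond = condition or Condition(name="cascade")
    clf = CascadeClassifier(
        patch_specs=tuple(patch_specs),
        channels=cond.channels,
        subnet_fc_units=cond.subnet_fc_units,
        fusion_fc_units=cond.fusion_fc_units,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        subnet_max_epochs=cfg.patch_max_epochs,
        fusion_max_epochs=cfg.max_epochs,
        patience=cfg.early_stop_patience,
        dropout=cfg.dropout,
        l2=cfg.l2,
        monitor=cfg.monitor,
        random_state=cfg.seed,
    )
    return clf.fit(X, y, X_val=X_val, y_val=y_val)


def grid_search(
    param_grid: Mapping[str, Sequence],
    make_estimator,
    X,
    y,
    cv: int = 5,
    seed: int = 0,
) -> dict:
    """Exhaustive hyperparameter search by k-fold CV mean accuracy.

    ``make_estimator(**params)`` must return an unfitted classifier.
    Returns the best parameter dict; ties are broken by the smallest
    learning rate, then the smallest batch size, then grid order.
    """
    from itertools import product

    from sklearn.model_selection import StratifiedKFold

    keys = list(param_grid)
    combos = [dict(zip(keys, vals)) for vals in product(*(param_grid[k] for k in keys))]
    if not combos:
        raise ValueError("empty hyperparameter grid")
    # deduplicate, preserving order
    seen, unique = set(), []
    for c in combos:
        key = tuple(sorted(c.items()))
        if key not in seen:
            seen.add(key)
            unique.append(c)
    y_arr = np.asarray(y)
    X_arr = np.asarray(X)
    results = []
    for params in unique:
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed % (2**32))
        accs = []
        for tr, te in skf.split(np.zeros(len(y_arr)), y_arr):
            est = make_estimator(**params)
            est.fit(X_arr[tr], y_arr[tr])
            accs.append(float((est.predict(X_arr[te]) == y_arr[te]).mean()))
        results.append((params, float(np.mean(accs))))
    best_acc = max(acc for _, acc in results)
    tied = [p for p, acc in results if acc >= best_acc - 1e-12]
    tied.sort(
        key=lambda p: (p.get("learning_rate", np.inf), p.get("batch_size", np.inf))
    )
    return tied[0]


def _stratified_half(records: list[SubjectRecord], rng: np.random.Generator) -> list[SubjectRecord]:
    """Keep a random stratified half of the training subjects (others dropped)."""
    keep: set[str] = set()
    for label in ("AD", "CN"):
        ids = sorted(r.subject_id for r in records if r.label == label and r.split == "train")
        n_keep = len(ids) // 2
        keep |= set(rng.choice(ids, size=n_keep, replace=False).tolist())
    out = []
    for r in records:
        if r.split == "train" and r.subject_id not in keep:
            continue
        out.append(r)
    return out


def _stack(records: Sequence[SubjectRecord], volumes: Mapping[str, Volume], split: str):
    recs = [r for r in records if r.split == split]
    X = np.stack([volumes[r.subject_id].data for r in recs])
    y = np.array([r.label for r in recs])
    return X, y, recs


def run_experiment(cfg: ExperimentConfig):
    """Run the full repeated comparison; returns (acc_table, metrics, reports).

    Per repetition: split (seeded by the global seed and the repetition
    index), optional stratified halving of the training set, matched
    undersampling of the test set, then every condition trained on the
    identical splits. Emits ``metrics.csv``, the repetitions × conditions
    accuracy table, and the ANOVA + Tukey report (``anova.json``) when an
    output directory is configured; per-repetition JSON files make the run
    resumable.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        (out_dir / "repetitions").mkdir(parents=True, exist_ok=True)
    records, volumes = generate_cohort_arrays(cfg.cohort)
    volume_shape = cfg.cohort.volume_shape
    rows: list[dict] = []
    for rep in range(cfg.n_repetitions):
        rep_file = out_dir / "repetitions" / f"rep{rep:03d}.json" if out_dir else None
        if rep_file and rep_file.exists():
            rows.extend(json.loads(rep_file.read_text()))
            continue
        rep_seed = _repetition_seed(cfg.seed, rep)
        split_cfg = SplitConfig(fractions=cfg.split_fractions, seed=rep_seed)
        assigned = stratified_split(records, split_cfg)
        if cfg.half_training:
            rng = np.random.default_rng(np.random.SeedSequence((rep_seed, 0xA1F)))
            assigned = _stratified_half(assigned, rng)
        test_recs = [r for r in assigned if r.split == "test"]
        balanced_test = undersample_match(test_recs, volumes)
        X_train, y_train, _ = _stack(assigned, volumes, "train")
        X_val, y_val, _ = _stack(assigned, volumes, "val")
        X_test = np.stack([volumes[r.subject_id].data for r in balanced_test])
        y_test = np.array([r.label for r in balanced_test])
        rep_rows = []
        for cond in cfg.conditions:
            train_cfg = replace(cfg.train, seed=rep_seed)
            try:
                specs = cond.patch_specs(volume_shape)
                if cond.method == "baseline":
                    spec = baseline_spec(
                        input_shape=volume_shape,
                        channels=cond.channels,
                        fc_units=cond.subnet_fc_units,
                    )
                    model = train_model(spec, X_train, y_train, X_val, y_val, train_cfg)
                else:
                    model = train_cascade(
                        specs, X_train, y_train, X_val, y_val, train_cfg, cond
                    )
                report = compute_metrics(y_test, model.score_positive(X_test))
                rep_rows.append(
                    {"repetition": rep, "condition": cond.name, "error": "",
                     **report.as_dict()}
                )
            except RuntimeError as exc:
                rep_rows.append(
                    {"repetition": rep, "condition": cond.name, "error": str(exc)}
                )
        if rep_file:
            rep_file.write_text(json.dumps(rep_rows))
        rows.extend(rep_rows)

    metrics = pd.DataFrame(rows)
    failed = metrics["error"].astype(bool).any() if "error" in metrics else False
    acc_table = metrics.pivot(index="repetition", columns="condition", values="acc")
    reports: dict = {}
    if not failed and len(cfg.conditions) >= 2 and cfg.n_repetitions >= 2:
        anova = rm_anova(acc_table)
        tukey = tukey_posthoc(acc_table)
        reports = {
            **anova.as_dict(),
            "tukey": tukey.to_dict(orient="records"),
        }
    elif failed:
        reports = {"error": "one or more conditions failed; ANOVA skipped"}
    if out_dir:
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        if reports:
            (out_dir / "anova.json").write_text(json.dumps(reports, indent=2))
    return acc_table, metrics, reports


# ---------------------------------------------------------------------------
# Desk-scale profile: proportionally shrunk so the whole pipeline runs on one
# CPU core in minutes while keeping every structural element of the design.


def desk_cohort_config(**overrides) -> CohortConfig:
    """A small cohort preserving the study's statistical structure.

    30×38×30 voxels (≈1/3 linear scale), one pair of mirrored atrophy
    sites, moderate effect size, the same noise and smoothness scales.
    """
    from .cohort import AtrophySite

    defaults = dict(
        n_subjects=40,
        class_fraction_ad=0.5,
        volume_shape=(30, 38, 30),
        voxel_size_mm=1.5,
        atrophy_sites=(
            AtrophySite(center=(10, 16, 11), radius=5.0, delta=0.4),
            AtrophySite(center=(20, 16, 11), radius=5.0, delta=0.4),
        ),
        heterogeneity_fraction=0.0,
        noise_sd=0.05,
        background_smoothness_mm=6.0,
        jitter_voxels=0.5,
        seed=0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def desk_train_config(**overrides) -> TrainConfig:
    """Shrunk schedule: larger step, fewer epochs, shorter patience."""
    defaults = dict(
        learning_rate=1e-3,
        batch_size=8,
        dropout=0.2,
        max_epochs=30,
        patch_max_epochs=25,
        early_stop_patience=6,
        l2=1e-4,
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


def desk_conditions(volume_shape=(30, 38, 30)) -> tuple[Condition, ...]:
    """Desk-scale analogues of the partition-method comparison."""
    small = dict(
        channels=(4, 8, 8, 16), subnet_fc_units=(32, 16), fusion_fc_units=(64, 32)
    )
    return (
        Condition(name="cubic-16", method="grid", patch_shape=(16, 16, 16),
                  counts=(2, 3, 2), **small),
        Condition(name="slab", method="grid",
                  patch_shape=(volume_shape[0], 16, volume_shape[2]),
                  counts=(1, 3, 1), **small),
        Condition(name="roi", method="roi", patch_shape=(16, 16, 16),
                  centers=((10, 16, 11), (20, 16, 11)), **small),
        Condition(name="baseline", method="baseline", **small),
    )
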