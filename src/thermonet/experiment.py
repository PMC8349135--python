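"""Desk-scale training/evaluation harness.

Reproduces the mechanics of the thermography experiment grids — optimizer
x learning-rate x epoch sweeps, stratified train/test splits, conv-prefix
freezing, configurable classifier heads, repeated runs with a mean ±
"marginal error" summary — on synthetic thermograms with the tiny
width-scaled network variants, so a full grid runs on one CPU in minutes.
Full-size 299x299 training is supported through the same interface but is
not the intended desk path.

Accuracies are reported in percent at epoch end (matching the per-epoch
layout of grid tables); the marginal error of a repeat summary is a
t-based 95% confidence half-width.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import builders, metrics, nn, synthgen, thermal_io
from .graph import TensorShape

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "RepeatSummary",
    "InsufficientRepeatsError",
    "train_and_evaluate",
    "run_grid",
    "pivot_results",
    "summarize_repeats",
    "GRID_AXES",
]

GRID_AXES = ("optimizer", "learning_rate", "epochs", "model", "train_fraction")

POSITIVE_LABEL = "sick"


def easy_simulation_config(seed: int = 123) -> synthgen.SimulationConfig:
    """The 'easy' synthetic setting for end-to-end smoke experiments:
    every lesion at the full 3 °C elevation over low (0.05 °C) sensor
    noise, other acquisition parameters at their defaults."""
    return synthgen.SimulationConfig(
        noise_sd=0.05, delta_t_range=(3.0, 3.0), seed=seed
    )


def flip_only_policy(seed: int = 0) -> thermal_io.AugmentationPolicy:
    """Left-right mirror augmentation alone — the cheap, anatomically
    meaningful slice of the full flip/translate/scale policy, used by the
    tiny training protocol."""
    return thermal_io.AugmentationPolicy(
        flip_vertical_axis=True, max_translation=0, max_scale_fraction=0.0,
        seed=seed,
    )


def easy_smoke_config(seed: int = 0, **overrides) -> "ExperimentConfig":
    """Tiny-MV4 training configuration for the easy synthetic setting:
    3 epochs, minibatch 10, 70/30 split, SGDM at the tiny-scale learning
    rate, mirror augmentation."""
    base = dict(
        model="tiny-mv4", optimizer="sgdm", learning_rate=0.0125, epochs=3,
        batch_size=10, train_fraction=0.7, augment=flip_only_policy(),
        seed=seed,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


class InsufficientRepeatsError(ValueError):
    """A repeat summary needs at least two runs."""


@dataclass(frozen=True)
class ExperimentConfig:
    """One training run's knobs.

    ``learning_rate`` follows the sweep convention 1e-2 .. 1e-6; minibatch
    defaults to 10.  ``freeze_convs`` marks that many leading conv layers
    non-trainable; ``freeze_stem`` freezes the whole stem region instead.
    ``shuffle_labels`` permutes labels across the dataset before splitting
    — the negative control, which destroys any image-label association.
    """

    model: str = "tiny-mv4"
    optimizer: str = "sgdm"
    learning_rate: float = 0.0125
    epochs: int = 3
    batch_size: int = 10
    train_fraction: float = 0.7
    freeze_convs: int = 0
    freeze_stem: bool = False
    head: builders.HeadSpec | None = None
    input_side: int | None = None
    augment: thermal_io.AugmentationPolicy | None = None
    shuffle_labels: bool = False
    seed: int = 0
    repeats: int = 1

    def __post_init__(self):
        if self.model not in builders.MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def side(self) -> int:
        if self.input_side is not None:
            return self.input_side
        return builders.TINY_SIDE if self.model.startswith("tiny-") else 299

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ExperimentConfig":
        doc = dict(doc)
        if "augment" in doc and isinstance(doc["augment"], Mapping):
            doc["augment"] = thermal_io.AugmentationPolicy(**doc["augment"])
        return cls(**doc)


@dataclass(frozen=True)
class RunResult:
    """Per-epoch accuracies (percent), final confusion counts and metric
    report on the held-out split, wall time (informational only)."""

    config: ExperimentConfig
    train_accuracy: tuple[float, ...]
    val_accuracy: tuple[float, ...]
    counts: metrics.ConfusionCounts | None
    report: metrics.MetricReport | None
    wall_time_s: float
    seed: int
    failed: bool = False

    @property
    def final_val_accuracy(self) -> float | None:
        return self.val_accuracy[-1] if self.val_accuracy else None

    def to_row(self) -> dict:
        c = self.counts
        return {
            "model": self.config.model,
            "optimizer": self.config.optimizer,
            "learning_rate": self.config.learning_rate,
            "epochs": self.config.epochs,
            "train_fraction": self.config.train_fraction,
            "seed": self.seed,
            "failed": self.failed,
            "val_accuracy": self.final_val_accuracy,
            "tp": c.tp if c else None,
            "tn": c.tn if c else None,
            "fp": c.fp if c else None,
            "fn": c.fn if c else None,
        }


@dataclass(frozen=True)
class RepeatSummary:
    """Mean accuracy with its t-interval half-width ("marginal error")."""

    mean_accuracy: float
    marginal_error: float
    n: int
    per_run: tuple[float, ...]
    minimum: float
    maximum: float
    confidence: float


# ---------------------------------------------------------------------------
# data preparation


def records_to_arrays(
    records: Sequence[thermal_io.ImageRecord], side: int
) -> tuple[np.ndarray, list[str]]:
    """Resize records to side x side x 3 and normalize to [0, 1] float32."""
    xs = []
    labels = []
    for rec in records:
        resized = thermal_io.resize_to_network(rec, side)
        px = resized.pixels.astype(np.float32)
        if np.issubdtype(resized.pixels.dtype, np.integer):
            px /= float(np.iinfo(resized.pixels.dtype).max)
        xs.append(px)
        labels.append(rec.label)
    return np.stack(xs), labels


def _onehot(labels: Sequence[str]) -> np.ndarray:
    out = np.zeros((len(labels), 2), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, 1 if lab == POSITIVE_LABEL else 0] = 1.0
    return out


def _accuracy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean() * 100.0)


# ---------------------------------------------------------------------------
# training


def train_and_evaluate(
    config: ExperimentConfig,
    records: Sequence[thermal_io.ImageRecord],
) -> RunResult:
    """Train the configured model on ``records`` and evaluate the held-out
    split.

    Fixed seed implies a deterministic run: the seed drives the label
    shuffle (negative control only), the stratified split, weight
    initialization, batch order, dropout and augmentation.  A non-finite
    loss flags the run as failed instead of raising.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    if config.shuffle_labels:
        labels = [r.label for r in records]
        perm = rng.permutation(len(labels))
        records = [
            thermal_io.ImageRecord(r.pixels, labels[perm[i]], r.source_id, r.color_mode)
            for i, r in enumerate(records)
        ]
    train_recs, val_recs = thermal_io.split_dataset(
        records, config.train_fraction, seed=config.seed
    )
    graph = builders.build_model(
        config.model,
        input_shape=TensorShape(config.side, config.side, 3),
        head=config.head,
    )
    if config.freeze_stem:
        graph = graph.freeze_region("stem")
    if config.freeze_convs:
        graph = graph.freeze_prefix(config.freeze_convs)

    x_train, lab_train = records_to_arrays(train_recs, config.side)
    x_val, lab_val = records_to_arrays(val_recs, config.side)
    y_train, y_val = _onehot(lab_train), _onehot(lab_val)

    executor = nn.NetworkExecutor(
        graph, TensorShape(config.side, config.side, 3), rng
    )
    optimizer = nn.make_optimizer(config.optimizer, config.learning_rate)

    train_acc: list[float] = []
    val_acc: list[float] = []
    failed = False
    n_train = len(x_train)
    step = 0
    base_lr = optimizer.lr
    # Polyak-Ruppert tail averaging: the weights evaluated after the final
    # epoch are the running average of the iterates visited during it,
    # which removes most of the minibatch-gradient jitter of a short run
    swa_sum: dict | None = None
    swa_n = 0
    for _epoch in range(config.epochs):
        final_epoch = _epoch == config.epochs - 1
        if config.augment is not None:
            xs = []
            for rec in train_recs:
                aug = thermal_io.augment(rec, config.augment, rng)
                xs.append(aug)
            x_epoch, _ = records_to_arrays(xs, config.side)
        else:
            x_epoch = x_train
        order = rng.permutation(n_train)
        correct = 0
        for start in range(0, n_train, config.batch_size):
            # linear warmup over the first 20 steps tames the large
            # early gradients of a freshly initialized deep net
            optimizer.lr = base_lr * min(1.0, (step + 1) / 20.0)
            step += 1
            idx = order[start : start + config.batch_size]
            loss, probs = executor.train_step(
                x_epoch[idx], y_train[idx], optimizer, rng
            )
            if not np.isfinite(loss):
                failed = True
                break
            correct += int((probs.argmax(axis=1) == y_train[idx].argmax(axis=1)).sum())
            if final_epoch:
                if swa_sum is None:
                    swa_sum = {
                        nid: {k: v.astype(np.float64).copy() for k, v in p.items()}
                        for nid, p in executor.params.items()
                    }
                else:
                    for nid, p in executor.params.items():
                        for k in p:
                            swa_sum[nid][k] += p[k]
                swa_n += 1
        if failed:
            break
        train_acc.append(100.0 * correct / n_train)
        if final_epoch and swa_sum is not None:
            for nid, p in executor.params.items():
                for k in p:
                    p[k] = (swa_sum[nid][k] / swa_n).astype(p[k].dtype)
        executor.recalibrate_batchnorm(x_train)
        val_probs = executor.predict_proba(x_val)
        val_acc.append(_accuracy(val_probs, y_val))

    counts = report = None
    if not failed and val_acc:
        val_probs = executor.predict_proba(x_val)
        predicted = [
            POSITIVE_LABEL if k else "healthy" for k in val_probs.argmax(axis=1)
        ]
        counts = metrics.confusion_from_predictions(lab_val, predicted, POSITIVE_LABEL)
        report = metrics.evaluate(counts)
    return RunResult(
        config=config,
        train_accuracy=tuple(train_acc),
        val_accuracy=tuple(val_acc),
        counts=counts,
        report=report,
        wall_time_s=time.perf_counter() - t0,
        seed=config.seed,
        failed=failed,
    )


# ---------------------------------------------------------------------------
# grids and repeats


def _cell_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(base_seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def run_grid(
    base_config: ExperimentConfig,
    axes: Mapping[str, Sequence],
    records: Sequence[thermal_io.ImageRecord],
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """One run per cell of the cartesian product of ``axes``.

    Axes may vary optimizer, learning_rate, epochs, model and
    train_fraction.  Cell seeds derive deterministically from the base
    seed, and with ``out_dir`` set each finished cell is written to a JSON
    file and skipped on re-run (cell-level resume).
    """
    if not axes:
        raise ValueError("axes must be non-empty")
    for key in axes:
        if key not in GRID_AXES:
            raise ValueError(f"unknown grid axis {key!r}; choose from {GRID_AXES}")
    keys = sorted(axes)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for index, values in enumerate(itertools.product(*(axes[k] for k in keys))):
        cell = dict(zip(keys, values))
        cell_path = out_dir / f"cell_{index:04d}.json" if out_dir else None
        if cell_path is not None and cell_path.exists():
            rows.append(json.loads(cell_path.read_text()))
            continue
        config = replace(base_config, seed=_cell_seed(base_config.seed, index), **cell)
        row = train_and_evaluate(config, records).to_row()
        if cell_path is not None:
            cell_path.write_text(json.dumps(row))
        rows.append(row)
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        frame.to_csv(out_dir / "results_long.csv", index=False)
        pivot_results(frame).to_csv(out_dir / "results_pivot.csv")
    return frame


def pivot_results(frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long results table into the grid-table layout: rows =
    epochs, columns = optimizer x learning rate, cells = accuracy."""
    return frame.pivot_table(
        index="epochs",
        columns=["optimizer", "learning_rate"],
        values="val_accuracy",
        aggfunc="mean",
    )


def summarize_repeats(
    accuracies: Sequence[float], confidence: float = 0.95
) -> RepeatSummary:
    """Mean of repeated-run accuracies with a t-based confidence
    half-width (the "marginal error"); identical runs give zero margin."""
    accs = [float(a) for a in accuracies]
    if len(accs) < 2:
        raise InsufficientRepeatsError("need at least 2 runs to summarize repeats")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    arr = np.asarray(accs)
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    tcrit = float(_stats.t.ppf((1.0 + confidence) / 2.0, df=n - 1))
    return RepeatSummary(
        mean_accuracy=mean,
        marginal_error=tcrit * sd / np.sqrt(n),
        n=n,
        per_run=tuple(accs),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        confidence=confidence,
    )
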