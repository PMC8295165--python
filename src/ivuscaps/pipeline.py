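"""End-to-end experiments: grouped cross-validation, training, evaluation.

Three data scenarios mirror the study design on a ten-patient dataset:

* ``s250`` — five training patients, fivefold cross-validation with every
  fold holding out all frames of one patient; the remaining patients form
  a fixed test set shared by all folds and scenarios.
* ``s150`` — the same scheme with a 60% per-patient frame subsample.
* ``s50``  — frames of a *single* training patient split into five folds
  (validation folds highly correlated with training data by design).

Training uses adaptive-moment gradient descent with on-the-fly rotation
and flip augmentation on training frames only, validates after every epoch
by the mean foreground Dice coefficient, and keeps the weights of the best
validation epoch (earliest epoch on ties).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.transform import resize as sk_resize

from . import autodiff as ad
from .capsule_math import PoseTreatment, RoutingSpec
from .capsule_network import (ArchitectureConfig, CapsuleUNet, UNetRes,
                              UNetResConfig)
from .losses import (MarginSchedule, generalized_dice_loss, margin_at,
                     spread_loss)
from .optim import Adam
from .phantom_data import PhantomSample, augment
from .seg_metrics import FOREGROUND_CLASSES, dice, evaluate_case, report_rows

__all__ = [
    "FoldScheme", "TrainConfig", "TrainingHistory",
    "make_folds", "resize_case", "contours_to_mask",
    "train_fold", "cross_validate", "save_checkpoint", "load_checkpoint",
    "config_to_yaml", "config_from_yaml",
]

SCENARIOS = ("s250", "s150", "s50")


@dataclass
class FoldScheme:
    """Grouped cross-validation folds plus a fixed common test set."""

    folds: list[tuple[list[int], list[int]]]   # (train ids, validation ids)
    test: list[int]
    grouping: str = "by_patient"               # or "within_patient"

    def __post_init__(self):
        test = set(self.test)
        for k, (train, val) in enumerate(self.folds):
            tr, va = set(train), set(val)
            if tr & va:
                raise ValueError(f"fold {k}: train and validation overlap")
            if (tr | va) & test:
                raise ValueError(f"fold {k}: test ids leak into training")


@dataclass
class TrainConfig:
    """Optimization settings.

    The capsule network trains with the spread loss at learning rate 1e-3;
    the residual U-Net baseline with the generalized Dice loss at 2e-4.
    """

    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 4
    loss: str = "spread"                       # or "generalized_dice"
    seed: int = 0
    margin_schedule: MarginSchedule = field(default_factory=MarginSchedule)
    augment: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("spread", "generalized_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingHistory:
    """Per-epoch validation mean foreground Dice and the selected epoch."""

    val_dice: list[float]
    checkpoint_index: int

    def __post_init__(self):
        if self.val_dice:
            best = int(np.argmax(self.val_dice))   # first occurrence on ties
            if best != self.checkpoint_index:
                raise ValueError("checkpoint index must be the argmax of "
                                 "validation Dice (first occurrence)")


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------

def make_folds(manifest: pd.DataFrame, scenario: str = "s250",
               n_folds: int = 5, subsample: float = 0.6,
               single_patient: str | None = None,
               seed: int = 0) -> FoldScheme:
    """Build the grouped cross-validation scheme for a scenario.

    The manifest needs ``index`` and ``patient_id`` columns.  The first
    ``n_folds`` patients (sorted by id) become training patients — one per
    fold — and all remaining patients form the common test set.  ``s150``
    subsamples ``subsample`` of each training patient's frames
    (deterministic given ``seed``); ``s50`` uses only ``single_patient``
    (default: the first training patient), split into ``n_folds`` chunks.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    patients = sorted(manifest["patient_id"].unique())
    if len(patients) <= n_folds:
        raise ValueError(
            f"need more than {n_folds} patients for a held-out test set, "
            f"got {len(patients)}")
    train_patients = patients[:n_folds]
    test_patients = patients[n_folds:]
    by_patient = {p: sorted(manifest.loc[manifest.patient_id == p, "index"])
                  for p in patients}
    test_ids = [i for p in test_patients for i in by_patient[p]]
    rng = np.random.default_rng(seed)

    if scenario in ("s250", "s150"):
        frames = {}
        for p in train_patients:
            ids = by_patient[p]
            if scenario == "s150":
                keep = max(1, int(round(subsample * len(ids))))
                ids = sorted(rng.choice(ids, size=keep, replace=False).tolist())
            frames[p] = ids
        folds = []
        for p in train_patients:
            val = frames[p]
            train = [i for q in train_patients if q != p for i in frames[q]]
            folds.append((train, val))
        return FoldScheme(folds, test_ids, grouping="by_patient")

    # s50: a single training patient's frames split into n_folds chunks
    patient = single_patient or train_patients[0]
    if patient not in by_patient:
        raise ValueError(f"unknown patient {patient!r}")
    ids = by_patient[patient]
    if len(ids) < n_folds:
        raise ValueError(f"patient {patient} has fewer frames than folds")
    chunks = [list(c) for c in np.array_split(ids, n_folds)]
    folds = []
    for k in range(n_folds):
        val = chunks[k]
        train = [i for j, c in enumerate(chunks) if j != k for i in c]
        folds.append((train, val))
    return FoldScheme(folds, test_ids, grouping="within_patient")


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def resize_case(image: np.ndarray, mask: np.ndarray, size: int):
    """Resize an image (bilinear) and its mask (nearest) to ``size**2``."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape == (size, size):
        return image, mask.copy()
    out_img = sk_resize(image, (size, size), order=1, anti_aliasing=True,
                        preserve_range=True)
    out_mask = sk_resize(mask, (size, size), order=0, anti_aliasing=False,
                         preserve_range=True).astype(mask.dtype)
    return out_img, out_mask


def contours_to_mask(lumen_contour, eem_contour, size: int) -> np.ndarray:
    """Rasterize lumen and external-elastic-membrane contours to a 3-class
    mask: inside lumen -> 2, inside EEM but outside lumen -> 1, else 0."""
    shape = (size, size)
    lumen = polygon2mask(shape, np.asarray(lumen_contour, dtype=float))
    eem = polygon2mask(shape, np.asarray(eem_contour, dtype=float))
    if np.any(lumen & ~eem):
        raise ValueError("lumen contour crosses outside the EEM contour")
    mask = np.zeros(shape, dtype=np.int64)
    mask[eem] = 1
    mask[lumen] = 2
    return mask


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _mean_foreground_dice(network, samples) -> float:
    scores = []
    for s in samples:
        pred = network.predict(s.image.astype(np.float32))
        scores.append(np.mean([dice(pred, s.mask, c) for c in FOREGROUND_CLASSES]))
    return float(np.mean(scores))


def _loss_for(network, sample, config: TrainConfig, epoch: int):
    out = network(sample.image.astype(np.float32))
    if config.loss == "spread":
        margin = margin_at(config.margin_schedule, epoch)
        return spread_loss(out, sample.mask, margin)
    return generalized_dice_loss(out, sample.mask)


def train_fold(network, train_samples: list[PhantomSample],
               val_samples: list[PhantomSample],
               config: TrainConfig,
               log=None) -> TrainingHistory:
    """Train one fold; the network is left holding the best-epoch weights.

    Augmentation (random rotation + flips) applies to training frames only.
    Raises on a non-finite loss with the epoch and sample for diagnosis.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters(), lr=config.learning_rate)
    history: list[float] = []
    best_state = None
    best_epoch = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                s = train_samples[idx]
                if config.augment:
                    s = augment(s, int(rng.integers(2 ** 31)))
                loss = _loss_for(network, s, config, epoch)
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss {value} at epoch {epoch}, "
                        f"sample {idx}; training aborted")
                loss.backward(np.asarray(1.0 / len(batch), dtype=np.float32))
            opt.step()
        val = _mean_foreground_dice(network, val_samples) if val_samples else 0.0
        history.append(val)
        if best_state is None or val > history[best_epoch]:
            best_epoch = epoch
            best_state = network.state_dict()
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs}: validation Dice {val:.2f}")
    if best_state is not None:
        network.load_state_dict(best_state)
    return TrainingHistory(history, best_epoch)


def cross_validate(samples: list[PhantomSample], scheme: FoldScheme,
                   network_factory, config: TrainConfig,
                   spacing: float | None = None, log=None) -> dict:
    """Train every fold, evaluate each best checkpoint on the common test
    set, and aggregate mean +/- standard deviation across folds.

    ``network_factory(fold_index)`` must return a freshly initialized
    network.  The report carries fold-level statistics per metric and class
    plus the per-image values for inspection.
    """
    fold_metrics = []
    per_image = []
    histories = []
    for k, (train_ids, val_ids) in enumerate(scheme.folds):
        net = network_factory(k)
        hist = train_fold(net, [samples[i] for i in train_ids],
                          [samples[i] for i in val_ids], config, log=log)
        histories.append(hist)
        rows = []
        for i in scheme.test:
            s = samples[i]
            pred = net.predict(s.image.astype(np.float32))
            rep = evaluate_case(pred, s.mask, spacing=spacing)
            for row in report_rows(rep, case=f"fold{k}/test{i}"):
                row["fold"] = k
                rows.append(row)
        per_image.extend(rows)
        frame = pd.DataFrame(rows)
        fold_means = (frame.dropna(subset=["value"])
                      .groupby(["class", "metric", "units"])["value"].mean())
        fold_metrics.append(fold_means)
    table = pd.concat(fold_metrics, axis=1)
    # a metric can be unavailable in some folds (class missing from every
    # predicted mask): mean over the folds that report it, std 0 when fewer
    # than two folds do
    summary = pd.DataFrame({
        "mean": table.mean(axis=1),
        "std": table.std(axis=1, ddof=1).fillna(0.0),
    }).reset_index()
    return {
        "summary": summary,
        "per_image": pd.DataFrame(per_image),
        "histories": histories,
    }


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def config_to_yaml(network_or_config) -> str:
    """Serialize an architecture config (capsule or baseline) as a YAML
    block with its kind tag, suitable for presets on disk."""
    import yaml

    if isinstance(network_or_config, ArchitectureConfig):
        kind = "capsnet"
    elif isinstance(network_or_config, UNetResConfig):
        kind = "unet_res"
    else:
        raise TypeError(f"unsupported config type {type(network_or_config)}")
    return yaml.safe_dump({"kind": kind,
                           "config": _config_to_dict(network_or_config)},
                          sort_keys=False)


def config_from_yaml(text: str):
    """Inverse of :func:`config_to_yaml`."""
    import yaml

    doc = yaml.safe_load(text)
    return _arch_from_dict(doc["kind"], doc["config"])


def _config_to_dict(obj):
    if isinstance(obj, (ArchitectureConfig, UNetResConfig)):
        d = asdict(obj)
        return d
    raise TypeError(f"unsupported config type {type(obj)}")


def _arch_from_dict(kind: str, d: dict):
    if kind == "capsnet":
        d = dict(d)
        d["routing"] = RoutingSpec(**d["routing"])
        d["pose_treatment"] = PoseTreatment(**d["pose_treatment"])
        d["shape"] = tuple(d["shape"])
        return ArchitectureConfig(**d)
    if kind == "unet_res":
        return UNetResConfig(**d)
    raise ValueError(f"unknown architecture kind {kind!r}")


def save_checkpoint(path, network, extra: dict | None = None) -> None:
    """Single-file weight archive with the architecture config embedded."""
    if isinstance(network, CapsuleUNet):
        kind = "capsnet"
    elif isinstance(network, UNetRes):
        kind = "unet_res"
    else:
        raise TypeError("unknown network type")
    meta = {"kind": kind, "config": _config_to_dict(network.config),
            "extra": extra or {}}
    state = network.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Rebuild the network (architecture + weights) from an archive."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = _arch_from_dict(meta["kind"], meta["config"])
    net = CapsuleUNet(cfg) if meta["kind"] == "capsnet" else UNetRes(cfg)
    net.load_state_dict(state)
    return net, meta
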