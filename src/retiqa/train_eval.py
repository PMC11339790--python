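"""Training loop, data splitting, and evaluation metrics.

Training follows the published protocol: Adam, minibatch 8, weight decay
5e-4, 20 epochs, learning rate 1e-3 for newly-added layers and one tenth
of that (1e-4) for the backbone, and the epoch with the highest test
accuracy kept as the final model.  Splits are stratified (80/20 holdout or
5-fold cross-validation); decisions binarize the sigmoid probability at a
0.5 threshold; discrimination is summarized by the ROC curve and its area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .model import ModelSpec, QualityModel, bce_loss, build_variant
from .nn import Tensor

__all__ = ["Hyperparams", "SplitSpec", "EvalResult", "UndefinedAUCError",
           "TrainingDivergedError", "stratified_split", "kfold_stratified",
           "train_model", "binarize", "evaluate", "predict_proba", "save_checkpoint",
           "load_checkpoint", "cross_validate"]


class UndefinedAUCError(ValueError):
    """AUC needs both classes; carries the accuracy that is still defined."""

    def __init__(self, msg: str, accuracy: float):
        super().__init__(msg)
        self.accuracy = accuracy


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class Hyperparams:
    """Published training settings; lr_backbone defaults to lr_new / 10."""

    batch_size: int = 8
    lr_new: float = 1e-3
    lr_backbone: float | None = None
    weight_decay: float = 5e-4
    epochs: int = 20
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr_backbone is None:
            object.__setattr__(self, "lr_backbone", self.lr_new / 10.0)
        for name in ("batch_size", "lr_new", "lr_backbone", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    stratify_on: str


@dataclass
class EvalResult:
    accuracy: float
    roc_points: np.ndarray  # (n, 2) ordered (FPR, TPR), (0,0) .. (1,1)
    auc: float


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(np.int64)


def stratified_split(table: pd.DataFrame, fraction: float = 0.8,
                     item: str = "overall", seed: int = 0) -> SplitSpec:
    """Seeded stratified holdout split on one label column.

    Per-class train counts land within one sample of `fraction`; the two
    index lists partition the table.
    """
    if len(table) == 0:
        raise ValueError("annotation table is empty")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    y = _check_labels(table[item].to_numpy())
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"stratification on {item!r} needs >= 2 members per class, "
            f"got {dict(zip([0, 1], counts.tolist()))}")
    idx = np.arange(len(table))
    tr, te = train_test_split(idx, train_size=fraction, stratify=y,
                              random_state=seed)
    return SplitSpec(np.sort(tr), np.sort(te), fraction, item)


def kfold_stratified(table: pd.DataFrame, k: int = 5, item: str = "overall",
                     seed: int = 0) -> list:
    """Stratified k-fold partition; each fold serves once as the test set."""
    y = _check_labels(table[item].to_numpy())
    if np.bincount(y, minlength=2).min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [SplitSpec(np.sort(tr), np.sort(te), 1.0 - 1.0 / k, item)
            for tr, te in skf.split(np.zeros(len(table)), y)]


def binarize(probabilities, threshold: float = 0.5) -> np.ndarray:
    """1 iff probability > threshold (strictly; 0.5 itself maps to 0)."""
    p = np.asarray(probabilities, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0,1]")
    return (p > threshold).astype(np.int64)


def evaluate(scores, labels, threshold: float = 0.5) -> EvalResult:
    """Accuracy at the threshold plus the ROC curve and its area.

    AUC uses trapezoidal integration over all score thresholds (the
    average-rank / Mann-Whitney convention for ties).  With a single class
    present, AUC is undefined: an :class:`UndefinedAUCError` carrying the
    accuracy is raised.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = _check_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    accuracy = float((binarize(scores, threshold) == labels).mean())
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC undefined with a single class", accuracy)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalResult(accuracy=accuracy,
                      roc_points=np.column_stack([fpr, tpr]), auc=auc)


# --- training ------------------------------------------------------------

def _batches(n, batch_size, rng=None):
    idx = np.arange(n) if rng is None else rng.permutation(n)
    for s in range(0, n, batch_size):
        yield idx[s:s + batch_size]


def predict_proba(model: QualityModel, images: np.ndarray,
                   masks: np.ndarray | None = None, batch_size: int = 8):
    model.eval()
    probs = []
    with nn.no_grad():
        for bi in _batches(len(images), batch_size):
            m = masks[bi] if masks is not None else None
            logit = model(Tensor(images[bi]), mask=m).data
            probs.append(1.0 / (1.0 + np.exp(-logit)))
    return np.concatenate(probs)


def train_model(model: QualityModel, train_data, test_data,
                hp: Hyperparams = Hyperparams(), verbose: bool = False):
    """Train a variant; returns (best state dict, history records).

    `train_data`/`test_data` are (images, labels) or (images, labels,
    masks) with images (N, 3, S, S) float32 in [0,1].  History holds one
    record per epoch (train loss, test accuracy); the returned parameters
    are those of the epoch with the highest test accuracy.
    """
    tr_imgs, tr_labels, tr_masks = (*train_data, None)[:3]
    te_imgs, te_labels, te_masks = (*test_data, None)[:3]
    if len(tr_imgs) == 0 or len(te_imgs) == 0:
        raise ValueError("train and test sets must be nonempty")
    tr_labels = _check_labels(tr_labels)
    te_labels = _check_labels(te_labels)
    backbone_params, new_params = model.parameter_groups()
    opt = nn.Adam([{"params": backbone_params, "lr": hp.lr_backbone},
                   {"params": new_params, "lr": hp.lr_new}],
                  weight_decay=hp.weight_decay)
    rng = np.random.default_rng(hp.seed)
    history, best = [], (-1.0, None)
    for epoch in range(hp.epochs):
        model.train()
        losses = []
        for bi in _batches(len(tr_imgs), hp.batch_size, rng):
            m = tr_masks[bi] if tr_masks is not None else None
            opt.zero_grad()
            loss = bce_loss(model(Tensor(tr_imgs[bi]), mask=m), tr_labels[bi])
            if not np.isfinite(loss.item()):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        probs = predict_proba(model, te_imgs, te_masks, hp.batch_size)
        acc = float((binarize(probs, hp.threshold) == te_labels).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "test_accuracy": acc})
        if acc > best[0]:
            best = (acc, model.state_dict())
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  "
                  f"test acc {acc:.3f}")
    model.load_state_dict(best[1])
    return best[1], history


def cross_validate(images: np.ndarray, table: pd.DataFrame, item: str,
                   spec: ModelSpec, hp: Hyperparams = Hyperparams(),
                   k: int = 5, masks: np.ndarray | None = None) -> list:
    """Stratified k-fold training; returns per-fold EvalResult list."""
    results = []
    for fold, split in enumerate(kfold_stratified(table, k, item, hp.seed)):
        model = build_variant(spec)
        y = table[item].to_numpy()
        tr = (images[split.train_indices], y[split.train_indices],
              masks[split.train_indices] if masks is not None else None)
        te = (images[split.test_indices], y[split.test_indices],
              masks[split.test_indices] if masks is not None else None)
        train_model(model, tr, te, hp)
        probs = predict_proba(model, te[0], te[2], hp.batch_size)
        results.append(evaluate(probs, te[1], hp.threshold))
    return results


# --- checkpointing -------------------------------------------------------

CHECKPOINT_SCHEMA = "retiqa-checkpoint-v1"


def save_checkpoint(path, model: QualityModel, history=None) -> None:
    """Single-file npz archive: schema tag, spec snapshot, tensors, history."""
    meta = {"schema": CHECKPOINT_SCHEMA,
            "spec": {"variant": model.spec.variant,
                     "backbone": model.spec.backbone,
                     "rescale_channels": list(model.spec.rescale_channels),
                     "sir_out_channels": model.spec.sir_out_channels,
                     "hidden": model.spec.hidden,
                     "threshold": model.spec.threshold,
                     "seed": model.spec.seed},
            "history": history or []}
    arrays = {"param:" + k: v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple:
    """Rebuild the model from a checkpoint; returns (model, history)."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unrecognized checkpoint schema: {meta.get('schema')}")
        s = meta["spec"]
        spec = ModelSpec(variant=s["variant"], backbone=s["backbone"],
                         rescale_channels=tuple(s["rescale_channels"]),
                         sir_out_channels=s["sir_out_channels"],
                         hidden=s["hidden"], threshold=s["threshold"],
                         seed=s["seed"])
        model = build_variant(spec)
        state = {k[len("param:"):]: archive[k] for k in archive.files
                 if k.startswith("param:")}
    model.load_state_dict(state)
    model.eval()
    return model, meta["history"]
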