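"""Stratified k-fold cross-validation training and ensembling.

Mirrors the study design: patients are split into k stratified folds
(stratification on the coarse class, since detailed classes can be rarer
than k); model i trains on all folds except i with early stopping on the
held-out fold's loss; at inference the k members' class-probability
vectors are averaged (which stays on the simplex), as are hemoglobin
predictions and (renormalized) attention weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .autograd import Adam, Tensor
from .hierarchy import LabelHierarchy, default_hierarchy
from .model import BagPrediction, BagTransformer, ModelConfig, build_model, subsample_bag
from .simulate import CellBag

__all__ = [
    "FoldPlan",
    "TrainParams",
    "Ensemble",
    "make_folds",
    "train_ensemble",
    "ensemble_predict",
    "predict_table",
]


@dataclass(frozen=True)
class FoldPlan:
    """Per-patient fold assignment, stratified by coarse class."""

    k: int
    seed: int
    assignments: Mapping[str, int]  # patient_id -> fold in {0..k-1}

    def fold_of(self, patient_id: str) -> int:
        return self.assignments[patient_id]


@dataclass(frozen=True)
class TrainParams:
    """Optimization settings shared by all ensemble members."""

    epochs: int = 40
    lr: float = 1e-3
    batch_size: int = 16
    k: int = 5
    patience: int = 6
    seed: int = 0


@dataclass
class Ensemble:
    """k trained members sharing one config and coarse-class order."""

    members: list[BagTransformer]
    class_order: tuple[str, ...]
    config: ModelConfig
    fold_plan: FoldPlan | None = None
    logs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")


def make_folds(manifest: pd.DataFrame, k: int, seed: int) -> FoldPlan:
    """Stratified fold assignment, reproducible from the seed.

    Within each coarse class, patients are shuffled and dealt round-robin
    into folds from a rotating starting fold, so per-fold class counts
    deviate from perfect proportionality by at most one patient.
    Raises if any class has fewer than k patients, naming the class.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    offset = 0
    for coarse, group in manifest.groupby("coarse_class", sort=True):
        ids = list(group["patient_id"])
        if len(ids) < k:
            raise ValueError(
                f"class {coarse!r} has only {len(ids)} patients; needs >= k={k}"
            )
        rng.shuffle(ids)
        for j, pid in enumerate(ids):
            assignments[pid] = (offset + j) % k
        offset += len(ids)
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def _batches(
    indices: np.ndarray,
    bags: Sequence[CellBag],
    batch_size: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Shuffled minibatches, grouped by bag size so batches stack."""
    by_size: dict[int, list[int]] = {}
    for i in indices:
        by_size.setdefault(bags[i].n_cells, []).append(i)
    batches = []
    for size in sorted(by_size):
        idx = np.array(by_size[size])
        rng.shuffle(idx)
        for s in range(0, len(idx), batch_size):
            batches.append(idx[s : s + batch_size])
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def _epoch_loss(
    model: BagTransformer,
    bags: Sequence[CellBag],
    y: np.ndarray,
    hb_z: np.ndarray,
    indices: np.ndarray,
    optimizer: Adam | None,
    rng: np.random.Generator,
    batch_size: int,
) -> tuple[float, float]:
    """One pass over ``indices``; trains if an optimizer is given.

    Returns (mean total loss per bag, accuracy).
    """
    w = model.config.hb_loss_weight
    total = 0.0
    correct = 0
    for batch in _batches(indices, bags, batch_size, rng):
        x = np.stack([bags[i].embeddings for i in batch])
        logits, hb_out, _, _ = model.forward(
            x, training=optimizer is not None, rng=rng
        )
        ce = logits.cross_entropy(y[batch])
        resid = hb_out - Tensor(hb_z[batch])
        batch_loss = ce + w * (resid * resid).mean()
        val = float(batch_loss.data)
        if not math.isfinite(val):
            raise RuntimeError(
                f"training diverged: non-finite loss {val} on a batch of "
                f"{len(batch)} bags"
            )
        total += val * len(batch)
        correct += int((logits.data.argmax(axis=1) == y[batch]).sum())
        if optimizer is not None:
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
    return total / len(indices), correct / len(indices)


def _snapshot(model: BagTransformer) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()]


def _restore(model: BagTransformer, snap: list[np.ndarray]) -> None:
    for p, s in zip(model.parameters(), snap):
        p.data = s.copy()


def train_ensemble(
    manifest: pd.DataFrame,
    bags: Sequence[CellBag],
    config: ModelConfig,
    params: TrainParams = TrainParams(),
    hierarchy: LabelHierarchy | None = None,
) -> Ensemble:
    """Train the k-fold ensemble on a cohort.

    With ``params.k == 1`` a single model is trained on all data with no
    validation split (degenerate smoke-test mode).  Bags larger than
    ``config.bag_size`` are subsampled once, without replacement, before
    training.  Fully deterministic given the seeds in config and params.
    """
    h = hierarchy or default_hierarchy()
    class_order = h.coarse_classes
    if config.n_classes != len(class_order):
        raise ValueError("config.n_classes must match the hierarchy")
    pids = list(manifest["patient_id"])
    if len(pids) != len(bags):
        raise ValueError("manifest and bags are misaligned")
    sub_rng = np.random.default_rng(params.seed + 1)
    bags = [subsample_bag(b, config.bag_size, sub_rng) for b in bags]
    y = np.array([class_order.index(c) for c in manifest["coarse_class"]])
    hb = manifest["hemoglobin"].to_numpy(dtype=float)

    plan = None
    if params.k > 1:
        plan = make_folds(manifest, params.k, params.seed)
        fold_ids = np.array([plan.fold_of(p) for p in pids])
    else:
        fold_ids = np.full(len(pids), -1)

    members: list[BagTransformer] = []
    logs: list[dict] = []
    for fold in range(params.k):
        train_idx = np.flatnonzero(fold_ids != fold)
        val_idx = np.flatnonzero(fold_ids == fold)
        model = build_model(replace(config, seed=config.seed + fold))
        # standardize hemoglobin on this member's training folds
        mu = float(hb[train_idx].mean())
        sd = float(hb[train_idx].std())
        model.hb_mean, model.hb_scale = mu, (sd if sd > 0 else 1.0)
        hb_z = (hb - model.hb_mean) / model.hb_scale
        optimizer = Adam(model.parameters(), lr=params.lr)
        rng = np.random.default_rng(params.seed * 1000 + fold)
        best_val = np.inf
        best_snap = _snapshot(model)
        since_best = 0
        for epoch in range(params.epochs):
            train_loss, train_acc = _epoch_loss(
                model, bags, y, hb_z, train_idx, optimizer, rng, params.batch_size
            )
            record = {
                "fold": fold,
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
            }
            if len(val_idx):
                val_loss, val_acc = _epoch_loss(
                    model, bags, y, hb_z, val_idx, None, rng, params.batch_size
                )
                record.update(val_loss=val_loss, val_acc=val_acc)
                if val_loss < best_val - 1e-6:
                    best_val, since_best = val_loss, 0
                    best_snap = _snapshot(model)
                else:
                    since_best += 1
            logs.append(record)
            if len(val_idx) and since_best >= params.patience:
                break
        if len(val_idx):
            _restore(model, best_snap)
        members.append(model)
    return Ensemble(
        members=members,
        class_order=class_order,
        config=config,
        fold_plan=plan,
        logs=logs,
    )


def ensemble_predict(ensemble: Ensemble, bag: CellBag | np.ndarray) -> BagPrediction:
    """Average member predictions: probabilities (simplex-preserving),
    hemoglobin, patient vector, and attention (renormalized to sum 1)."""
    preds = [m.predict_bag(bag) for m in ensemble.members]
    probs = np.mean([p.class_probabilities for p in preds], axis=0)
    attn = np.mean([p.attention_weights for p in preds], axis=0)
    attn = attn / attn.sum()
    return BagPrediction(
        class_probabilities=probs,
        hemoglobin_predicted=float(np.mean([p.hemoglobin_predicted for p in preds])),
        patient_vector=np.mean([p.patient_vector for p in preds], axis=0),
        attention_weights=attn,
    )


def predict_table(
    ensemble: Ensemble, bags: Sequence[CellBag], hierarchy: LabelHierarchy | None = None
) -> pd.DataFrame:
    """Ensemble predictions for many bags as a tidy table.

    Columns: patient_id, one probability column per coarse class (named,
    not indexed), predicted_hb.
    """
    h = hierarchy or default_hierarchy()
    if tuple(ensemble.class_order) != tuple(h.coarse_classes):
        raise ValueError("ensemble class order does not match the hierarchy")
    rows = []
    for bag in bags:
        pred = ensemble_predict(ensemble, bag)
        row = {"patient_id": bag.patient_id}
        for cls, p in zip(ensemble.class_order, pred.class_probabilities):
            row[f"p_{cls}"] = p
        row["predicted_hb"] = pred.hemoglobin_predicted
        rows.append(row)
    return pd.DataFrame(rows)
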