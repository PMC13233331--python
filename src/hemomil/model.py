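"""Transformer bag aggregator with a multi-task head.

A patient is a *bag* of single-cell embedding vectors (default width 768,
as produced by hematology image foundation encoders).  Cells are treated
as a set: the model projects each cell into a latent space (default 512),
prepends a learnable aggregation token, and runs pre-norm transformer
blocks *without positional encodings*.  The aggregation token's output is
the patient-level representation; a small MLP on top predicts the 8
coarse-class logits and, as an auxiliary regression task, the patient's
hemoglobin value on a standardized scale.

The aggregation token's attention row in the final block, averaged over
heads and renormalized over the cell positions, is exported as the
per-cell relevance weight used for explanation.

Outputs are permutation invariant in the bag order (attention weights are
permutation *equivariant*), and the model accepts bags of any size >= 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Adam, Tensor, concatenate
from .simulate import CellBag

__all__ = [
    "ModelConfig",
    "BagPrediction",
    "BagTransformer",
    "build_model",
    "loss",
    "subsample_bag",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss hyperparameters.

    ``hb_loss_weight`` scales the squared-error hemoglobin term relative
    to the classification cross-entropy; hemoglobin is standardized on the
    training folds so the two terms are commensurate.
    """

    embedding_dim: int = 768
    bag_size: int = 500
    latent_dim: int = 512
    n_heads: int = 8
    n_layers: int = 2
    n_classes: int = 8
    hb_loss_weight: float = 0.5
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim % self.n_heads != 0:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be divisible by "
                f"n_heads ({self.n_heads})"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if min(self.embedding_dim, self.bag_size, self.latent_dim, self.n_layers) < 1:
            raise ValueError("dimensions must be positive")
        if self.hb_loss_weight < 0:
            raise ValueError("hb_loss_weight must be nonnegative")


@dataclass
class BagPrediction:
    """Model output for one bag."""

    class_probabilities: np.ndarray  # (n_classes,), simplex
    hemoglobin_predicted: float  # g/dL, de-standardized
    patient_vector: np.ndarray  # (latent_dim,)
    attention_weights: np.ndarray  # (n_cells,), simplex

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probabilities, float)
        a = np.asarray(self.attention_weights, float)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite prediction values")
        if abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-12):
            raise ValueError("class probabilities must lie on the simplex")
        if abs(a.sum() - 1.0) > 1e-6 or np.any(a < -1e-12):
            raise ValueError("attention weights must lie on the simplex")
        self.class_probabilities = p
        self.attention_weights = a
        self.patient_vector = np.asarray(self.patient_vector, float)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class _Block:
    """One pre-norm transformer block (self-attention + 2-layer MLP)."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int):
        self.d = d
        self.h = n_heads
        self.dh = d // n_heads
        t = lambda a: Tensor(a, requires_grad=True)
        self.ln1_g = t(np.ones(d))
        self.ln1_b = t(np.zeros(d))
        self.wq = t(_xavier(rng, d, d))
        self.wk = t(_xavier(rng, d, d))
        self.wv = t(_xavier(rng, d, d))
        self.wo = t(_xavier(rng, d, d))
        self.bo = t(np.zeros(d))
        self.ln2_g = t(np.ones(d))
        self.ln2_b = t(np.zeros(d))
        hidden = 2 * d
        self.w1 = t(_xavier(rng, d, hidden))
        self.b1 = t(np.zeros(hidden))
        self.w2 = t(_xavier(rng, hidden, d))
        self.b2 = t(np.zeros(d))

    def parameters(self) -> list[Tensor]:
        return [
            self.ln1_g, self.ln1_b, self.wq, self.wk, self.wv, self.wo, self.bo,
            self.ln2_g, self.ln2_b, self.w1, self.b1, self.w2, self.b2,
        ]

    def _split_heads(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.h, self.dh).swapaxes(1, 2)  # (B,H,T,dh)

    def forward(self, x: Tensor, drop_mask=None) -> tuple[Tensor, np.ndarray]:
        """Returns (output, attention) with attention (B, H, T, T)."""
        B, T, _ = x.shape
        xn = x.layer_norm(self.ln1_g, self.ln1_b)
        q = self._split_heads(xn @ self.wq, B, T)
        k = self._split_heads(xn @ self.wk, B, T)
        v = self._split_heads(xn @ self.wv, B, T)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, self.d)
        x = x + (ctx @ self.wo + self.bo)
        xn2 = x.layer_norm(self.ln2_g, self.ln2_b)
        hdn = (xn2 @ self.w1 + self.b1).relu()
        if drop_mask is not None:
            hdn = hdn * drop_mask
        x = x + (hdn @ self.w2 + self.b2)
        return x, attn.data


class BagTransformer:
    """Set transformer over cell embeddings with an aggregation token."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.latent_dim
        t = lambda a: Tensor(a, requires_grad=True)
        self.w_in = t(_xavier(rng, config.embedding_dim, d))
        self.b_in = t(np.zeros(d))
        self.cls = t(rng.normal(scale=0.02, size=(1, 1, d)))
        self.blocks = [_Block(rng, d, config.n_heads) for _ in range(config.n_layers)]
        self.ln_f_g = t(np.ones(d))
        self.ln_f_b = t(np.zeros(d))
        self.w_trunk = t(_xavier(rng, d, d))
        self.b_trunk = t(np.zeros(d))
        self.w_cls = t(_xavier(rng, d, config.n_classes))
        self.b_cls = t(np.zeros(config.n_classes))
        self.w_hb = t(_xavier(rng, d, 1))
        self.b_hb = t(np.zeros(1))
        # hemoglobin standardization constants (set when training)
        self.hb_mean: float = 0.0
        self.hb_scale: float = 1.0

    def parameters(self) -> list[Tensor]:
        params = [self.w_in, self.b_in, self.cls]
        for blk in self.blocks:
            params.extend(blk.parameters())
        params.extend(
            [self.ln_f_g, self.ln_f_b, self.w_trunk, self.b_trunk,
             self.w_cls, self.b_cls, self.w_hb, self.b_hb]
        )
        return params

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor, np.ndarray, np.ndarray]:
        """Run a batch of equal-size bags.

        Parameters
        ----------
        x : (B, n_cells, embedding_dim) array.

        Returns
        -------
        logits : Tensor (B, n_classes)
        hb_std : Tensor (B,) hemoglobin on the standardized scale
        attention : ndarray (B, n_cells), aggregation-token attention of
            the final block, head-averaged and renormalized over cells
        patient_vectors : ndarray (B, latent_dim)
        """
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[-1] != self.config.embedding_dim:
            raise ValueError(
                f"expected (B, n, {self.config.embedding_dim}) input, got {x.shape}"
            )
        if x.shape[1] < 1:
            raise ValueError("bags must contain at least one cell")
        B, n, _ = x.shape
        h = Tensor(x) @ self.w_in + self.b_in
        cls = self.cls.broadcast_to((B, 1, self.config.latent_dim))
        h = concatenate([cls, h], axis=1)  # aggregation token at position 0
        p_drop = self.config.dropout if training else 0.0
        attn_last = None
        for blk in self.blocks:
            mask = None
            if p_drop > 0.0:
                if rng is None:
                    rng = np.random.default_rng(self.config.seed)
                keep = (rng.random((B, n + 1, 2 * self.config.latent_dim)) >= p_drop)
                mask = Tensor(keep / (1.0 - p_drop))
            h, attn_last = blk.forward(h, drop_mask=mask)
        h = h.layer_norm(self.ln_f_g, self.ln_f_b)
        pooled = h[:, 0, :]  # (B, d) aggregation-token output
        trunk = (pooled @ self.w_trunk + self.b_trunk).relu()
        logits = trunk @ self.w_cls + self.b_cls
        hb_std = (trunk @ self.w_hb + self.b_hb).reshape(B)
        # aggregation-token attention over cells: row 0, drop the token's
        # self-attention column, head-average, renormalize
        a = attn_last[:, :, 0, 1:].mean(axis=1)  # (B, n)
        a = a / a.sum(axis=1, keepdims=True)
        return logits, hb_std, a, pooled.data

    def predict_bag(self, bag: CellBag | np.ndarray) -> BagPrediction:
        """Predict a single (variable-size) bag."""
        emb = bag.embeddings if isinstance(bag, CellBag) else np.asarray(bag, float)
        if emb.ndim != 2:
            raise ValueError("bag must be a (n_cells, embedding_dim) matrix")
        logits, hb_std, attn, vec = self.forward(emb[None])
        probs = _softmax_1d(logits.data[0])
        hb = self.hb_mean + self.hb_scale * float(hb_std.data[0])
        return BagPrediction(
            class_probabilities=probs,
            hemoglobin_predicted=hb,
            patient_vector=vec[0],
            attention_weights=attn[0],
        )


def _softmax_1d(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def build_model(config: ModelConfig) -> BagTransformer:
    """Construct a model with deterministic seed-derived initialization."""
    return BagTransformer(config)


def loss(
    pred: BagPrediction,
    true_class: int,
    true_hb: float,
    config: ModelConfig,
    hb_scale: float = 1.0,
) -> tuple[float, float, float]:
    """Reporting loss for one prediction.

    ``total = cross_entropy + hb_loss_weight * squared_error`` with the
    hemoglobin residual divided by ``hb_scale`` (the training-fold
    standard deviation when available, 1 g/dL otherwise).
    """
    if not (0 <= true_class < len(pred.class_probabilities)):
        raise ValueError(f"true_class {true_class} out of range")
    if not np.isfinite(true_hb):
        raise ValueError("true_hb must be finite")
    p = float(pred.class_probabilities[true_class])
    ce = float(-np.log(max(p, 1e-300)))
    reg = float(((pred.hemoglobin_predicted - true_hb) / hb_scale) ** 2)
    return ce + config.hb_loss_weight * reg, ce, reg


def subsample_bag(bag: CellBag, bag_size: int, seed: int | np.random.Generator) -> CellBag:
    """Uniform subsample without replacement; small bags pass through."""
    if bag_size < 1:
        raise ValueError("bag_size must be >= 1")
    if bag.n_cells <= bag_size:
        return bag
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(bag.n_cells, size=bag_size, replace=False)
    return CellBag(
        patient_id=bag.patient_id,
        embeddings=bag.embeddings[idx],
        cell_types=None if bag.cell_types is None else bag.cell_types[idx],
        latent_blast_fraction=bag.latent_blast_fraction,
    )


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(
    model: BagTransformer, path: str | Path, class_order: Sequence[str]
) -> None:
    """Serialize parameters, config, class order and hb constants."""
    header = {
        "config": asdict(model.config),
        "class_order": list(class_order),
        "hb_mean": model.hb_mean,
        "hb_scale": model.hb_scale,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path: str | Path, class_order: Sequence[str]) -> BagTransformer:
    """Load a checkpoint; refuses if the stored class order differs."""
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        if header["class_order"] != list(class_order):
            raise ValueError(
                "checkpoint class order "
                f"{header['class_order']} does not match active hierarchy "
                f"{list(class_order)}"
            )
        model = BagTransformer(ModelConfig(**header["config"]))
        for i, p in enumerate(model.parameters()):
            stored = npz[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = stored.copy()
        model.hb_mean = float(header["hb_mean"])
        model.hb_scale = float(header["hb_scale"])
    return model
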