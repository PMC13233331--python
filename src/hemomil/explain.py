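"""Cell-level explanations of bag predictions.

For one patient this produces the programmatic equivalent of a diagnostic
report card: class probabilities, predicted hemoglobin, malignancy
probability, the ensemble-averaged attention weight of every cell, and —
to relate individual cells to diseases — each cell run through the model
as a singleton bag, yielding a per-cell class probability vector and
argmax class.  In an informative model, diagnostically relevant cells
(e.g. myeloblasts in acute leukemia) concentrate the attention mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hierarchy import LabelHierarchy
from .metrics import malignancy_probability
from .simulate import CellBag
from .training import Ensemble, ensemble_predict

__all__ = ["AttentionReport", "explain", "top_cells"]


@dataclass
class AttentionReport:
    """Per-patient explanation artifact."""

    patient_id: str
    class_order: tuple[str, ...]
    class_probabilities: np.ndarray  # (n_classes,)
    malignancy_prob: float
    hemoglobin_predicted: float  # g/dL
    attention_weights: np.ndarray  # (n_cells,), sums to 1
    cell_probabilities: np.ndarray  # (n_cells, n_classes) singleton-bag rows
    cell_classes: list[str]  # singleton-bag argmax class per cell
    attention_entropy: float  # nats

    def to_frame(self) -> pd.DataFrame:
        """Per-cell records as a tidy table."""
        df = pd.DataFrame(
            {
                "cell_index": np.arange(len(self.attention_weights)),
                "attention": self.attention_weights,
                "cell_class": self.cell_classes,
            }
        )
        for j, cls in enumerate(self.class_order):
            df[f"p_{cls}"] = self.cell_probabilities[:, j]
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "class_probabilities": dict(
                    zip(self.class_order, map(float, self.class_probabilities))
                ),
                "malignancy_probability": self.malignancy_prob,
                "hemoglobin_predicted": self.hemoglobin_predicted,
                "attention_entropy_nats": self.attention_entropy,
                "cells": self.to_frame().to_dict(orient="records"),
            },
            indent=1,
        )

    def summary(self, m: int = 5) -> str:
        """Plain-text report card."""
        lines = [f"patient {self.patient_id}"]
        order = np.argsort(-self.class_probabilities, kind="stable")
        for j in order[:3]:
            lines.append(
                f"  {self.class_order[j]:<22s} {self.class_probabilities[j]:.3f}"
            )
        lines.append(f"  malignancy probability  {self.malignancy_prob:.3f}")
        lines.append(f"  predicted hemoglobin    {self.hemoglobin_predicted:.2f} g/dL")
        lines.append(f"  attention entropy       {self.attention_entropy:.2f} nats")
        lines.append(f"  top-{m} attended cells:")
        for i in top_cells(self, min(m, len(self.attention_weights))):
            lines.append(
                f"    cell {i:4d}  attention {self.attention_weights[i]:.4f}"
                f"  -> {self.cell_classes[i]}"
            )
        return "\n".join(lines)


def explain(ensemble: Ensemble, bag: CellBag, h: LabelHierarchy) -> AttentionReport:
    """Build the explanation report for one bag.

    Bag-level outputs come from the ensemble; per-cell outputs from
    passing each cell as a singleton bag through every member (batched)
    and averaging the probability rows. Deterministic for a fixed
    ensemble and bag.
    """
    if tuple(ensemble.class_order) != tuple(h.coarse_classes):
        raise ValueError("ensemble class order does not match the hierarchy")
    pred = ensemble_predict(ensemble, bag)
    n = bag.n_cells
    singles = bag.embeddings[:, None, :]  # n singleton bags, batched
    cell_probs = np.zeros((n, len(h.coarse_classes)))
    for member in ensemble.members:
        logits, _, _, _ = member.forward(singles)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        cell_probs += e / e.sum(axis=1, keepdims=True)
    cell_probs /= len(ensemble.members)
    cell_classes = [h.coarse_classes[j] for j in cell_probs.argmax(axis=1)]
    a = pred.attention_weights
    entropy = float(-(a * np.log(np.maximum(a, 1e-300))).sum())
    return AttentionReport(
        patient_id=bag.patient_id,
        class_order=tuple(h.coarse_classes),
        class_probabilities=pred.class_probabilities,
        malignancy_prob=malignancy_probability(pred.class_probabilities, h),
        hemoglobin_predicted=pred.hemoglobin_predicted,
        attention_weights=a,
        cell_probabilities=cell_probs,
        cell_classes=cell_classes,
        attention_entropy=entropy,
    )


def top_cells(report: AttentionReport, m: int) -> list[int]:
    """Indices of the m most-attended cells, descending weight.

    Ties resolve to the lower cell index (stable sort on descending
    weight).
    """
    n = len(report.attention_weights)
    if not (1 <= m <= n):
        raise ValueError(f"m must be in [1, {n}]")
    order = np.argsort(-report.attention_weights, kind="stable")
    return [int(i) for i in order[:m]]
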