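"""Malignancy triage and the evaluation suite.

The triage rule sums the predicted probabilities of the six malignant
coarse classes into a malignancy probability; if it exceeds the decision
threshold (0.5 by default, strict comparison) a bone marrow biopsy is
recommended.  Sweeping the threshold trades malignancy sensitivity
against the *aspiration FDR* — the fraction of biopsy-recommended
patients whose true condition is non-malignant, i.e. the unnecessary
biopsy rate.  The clinical baseline FDR is computed from per-class
patient counts as reactive / (reactive + malignant), excluding healthy
donors from the denominator since they are not aspirated for diagnosis.

Also here: confusion matrices with per-class sensitivity/precision,
top-k accuracy (ties broken by the fixed class order), top-label expected
calibration error with equal-width bins, rank-based AUROC, and the
agreement metrics used for hemoglobin and probability-vs-cell-ratio
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import LabelHierarchy

__all__ = [
    "TriageDecision",
    "ThresholdSweepResult",
    "EvaluationReport",
    "malignancy_probability",
    "triage",
    "threshold_sweep",
    "clinical_baseline_fdr",
    "confusion_and_rates",
    "detailed_confusion",
    "topk_accuracy",
    "expected_calibration_error",
    "auroc",
    "hemoglobin_agreement",
    "rank_correlation",
    "evaluate",
]


@dataclass(frozen=True)
class TriageDecision:
    malignancy_probability: float
    threshold: float
    recommend_biopsy: bool


@dataclass
class ThresholdSweepResult:
    """Per-threshold triage metrics.

    ``table`` columns: threshold, n_recommended, malignancy_sensitivity,
    malignancy_specificity, aspiration_fdr, acute_leukemia_sensitivity.
    Undefined rates (empty denominators) are NaN, never silently 0 or 1.
    """

    table: pd.DataFrame
    best_full_al_sensitivity_threshold: float | None
    fdr_at_best: float | None


def _check_simplex(p: np.ndarray, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"expected a length-{n} probability vector, got {p.shape}")
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-9):
        raise ValueError("probabilities must lie on the simplex")
    return p


def malignancy_probability(p: Sequence[float], h: LabelHierarchy) -> float:
    """Sum of predicted probabilities over the six malignant classes.

    Algebraically equals 1 - P(reactive changes) - P(healthy).
    """
    p = _check_simplex(p, len(h.coarse_classes))
    mal = [h.malignant_flags[c] for c in h.coarse_classes]
    return float(p[np.asarray(mal)].sum())


def triage(
    p: Sequence[float], h: LabelHierarchy, threshold: float = 0.5
) -> TriageDecision:
    """Biopsy recommendation: malignancy probability strictly above threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    mp = malignancy_probability(p, h)
    return TriageDecision(mp, threshold, recommend_biopsy=mp > threshold)


def threshold_sweep(
    predictions: Sequence[Sequence[float]],
    truth: Sequence[str],
    h: LabelHierarchy,
    thresholds: Sequence[float] | None = None,
    acute_leukemia_class: str = "acute leukemia",
) -> ThresholdSweepResult:
    """Triage metrics along an ascending threshold grid.

    Reports, per threshold: malignancy sensitivity and specificity, the
    aspiration FDR among recommended patients, and the sensitivity for
    the acute-leukemia class (NaN if no such patients).  Also reports the
    largest grid threshold retaining acute-leukemia sensitivity 1.0 and
    the FDR there.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    truth = list(truth)
    if len(truth) != len(predictions):
        raise ValueError("predictions and truth are misaligned")
    scores = np.array([malignancy_probability(p, h) for p in predictions])
    is_mal = np.array([h.malignant_flags[c] for c in truth])
    is_al = np.array([c == acute_leukemia_class for c in truth])
    rows = []
    for t in thresholds:
        rec = scores > t
        n_rec = int(rec.sum())
        tp = int((rec & is_mal).sum())
        fp = n_rec - tp
        n_mal = int(is_mal.sum())
        n_ben = len(truth) - n_mal
        rows.append(
            {
                "threshold": t,
                "n_recommended": n_rec,
                "malignancy_sensitivity": tp / n_mal if n_mal else np.nan,
                "malignancy_specificity": ((~rec & ~is_mal).sum() / n_ben)
                if n_ben
                else np.nan,
                "aspiration_fdr": fp / n_rec if n_rec else np.nan,
                "acute_leukemia_sensitivity": (rec & is_al).sum() / is_al.sum()
                if is_al.sum()
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    best_t = None
    best_fdr = None
    if is_al.sum():
        full = table[table["acute_leukemia_sensitivity"] >= 1.0]
        if len(full):
            idx = full["threshold"].idxmax()
            best_t = float(table.loc[idx, "threshold"])
            best_fdr = float(table.loc[idx, "aspiration_fdr"])
    return ThresholdSweepResult(table, best_t, best_fdr)


def clinical_baseline_fdr(class_counts: Mapping[str, int], h: LabelHierarchy) -> float:
    """Unnecessary-aspiration rate of the clinical pathway.

    Every reactive-changes and malignant-class patient is assumed to have
    been aspirated; healthy donors are not part of the diagnostic pathway
    and are excluded.  Returns reactive / (reactive + malignant counts).
    """
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("class counts must be nonnegative")
    reactive = class_counts.get("reactive changes", 0)
    malignant = sum(
        class_counts.get(c, 0) for c in h.coarse_classes if h.malignant_flags[c]
    )
    denom = reactive + malignant
    return reactive / denom if denom else 0.0


def confusion_and_rates(
    truth: Sequence[str], predicted: Sequence[str], class_order: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (rows = truth) with per-class sensitivity/precision.

    Precision for a class that was never predicted is NaN (missing), not
    zero.  Returns (matrix, rates) where rates has columns sensitivity,
    precision, support.
    """
    class_order = list(class_order)
    for lab in list(truth) + list(predicted):
        if lab not in class_order:
            raise ValueError(f"label {lab!r} not in class order")
    n = len(class_order)
    idx = {c: i for i, c in enumerate(class_order)}
    mat = np.zeros((n, n), dtype=int)
    for t, p in zip(truth, predicted, strict=True):
        mat[idx[t], idx[p]] += 1
    cm = pd.DataFrame(mat, index=class_order, columns=class_order)
    support = mat.sum(axis=1)
    pred_count = mat.sum(axis=0)
    tp = np.diag(mat)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(support > 0, tp / np.maximum(support, 1), np.nan)
        prec = np.where(pred_count > 0, tp / np.maximum(pred_count, 1), np.nan)
    rates = pd.DataFrame(
        {"sensitivity": sens, "precision": prec, "support": support},
        index=class_order,
    )
    return cm, rates


def detailed_confusion(
    truth_detailed: Sequence[str],
    predicted_coarse: Sequence[str],
    h: LabelHierarchy,
) -> tuple[pd.DataFrame, pd.Series]:
    """Detailed-truth vs coarse-prediction confusion.

    A detailed-class patient counts as correct when the predicted coarse
    class equals its own coarse class; the returned Series holds that
    per-detailed-class sensitivity.
    """
    det_order = sorted(set(truth_detailed))
    mat = pd.DataFrame(
        0, index=det_order, columns=list(h.coarse_classes), dtype=int
    )
    for d, p in zip(truth_detailed, predicted_coarse, strict=True):
        mat.loc[d, p] += 1
    sens = pd.Series(
        {
            d: mat.loc[d, h.map_label(d)[1]] / mat.loc[d].sum()
            for d in det_order
        },
        name="sensitivity",
    )
    return mat, sens


def topk_accuracy(
    probabilities: Sequence[Sequence[float]],
    truth_indices: Sequence[int],
    k: int,
) -> float:
    """Fraction of cases whose true class is among the k most probable.

    Ties are broken by the fixed class order (lower index wins), via a
    stable sort on descending probability.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    probs = np.asarray(probabilities, dtype=float)
    truth_indices = np.asarray(truth_indices, dtype=int)
    hits = 0
    for p, t in zip(probs, truth_indices, strict=True):
        top = np.argsort(-p, kind="stable")[:k]
        hits += int(t in top)
    return hits / len(truth_indices)


def expected_calibration_error(
    probabilities: Sequence[Sequence[float]],
    truth_indices: Sequence[int],
    n_bins: int = 10,
) -> float:
    """Top-label ECE with equal-width confidence bins over (0, 1].

    Patients are binned by their maximum predicted probability; the ECE
    is the support-weighted mean absolute gap between each bin's accuracy
    and its mean confidence.  Empty bins contribute nothing.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    probs = np.asarray(probabilities, dtype=float)
    truth_indices = np.asarray(truth_indices, dtype=int)
    conf = probs.max(axis=1)
    pred = probs.argmax(axis=1)
    correct = (pred == truth_indices).astype(float)
    n = len(conf)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # bins are (edge_{i}, edge_{i+1}]: confidence 0 would fall in bin 0
    bin_idx = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        mask = bin_idx == b
        if not mask.any():
            continue
        ece += (mask.sum() / n) * abs(correct[mask].mean() - conf[mask].mean())
    return float(ece)


def auroc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) AUROC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # mean ranks handle ties as half credit
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def hemoglobin_agreement(
    predicted: Sequence[float], measured: Sequence[float]
) -> tuple[float, float]:
    """(Pearson r, mean absolute error in g/dL) of predicted vs measured."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    ok = np.isfinite(predicted) & np.isfinite(measured)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    r = stats.pearsonr(predicted[ok], measured[ok]).statistic
    mae = float(np.abs(predicted[ok] - measured[ok]).mean())
    return float(r), mae


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho and p-value (e.g. class probability vs cell ratio)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    res = stats.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """Full evaluation of a predictions table against a manifest."""

    coarse_confusion: pd.DataFrame
    coarse_rates: pd.DataFrame
    detailed_confusion_matrix: pd.DataFrame
    detailed_sensitivity: pd.Series
    accuracy: float
    topk: dict[int, float]
    auroc_malignant: float
    ece: float
    hb_pearson: float | None
    hb_mae: float | None
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "topk": {str(k): v for k, v in self.topk.items()},
            "auroc_malignant": self.auroc_malignant,
            "ece": self.ece,
            "hb_pearson": self.hb_pearson,
            "hb_mae": self.hb_mae,
            "coarse_confusion": self.coarse_confusion.to_dict(),
            "coarse_rates": self.coarse_rates.replace({np.nan: None}).to_dict(),
            "detailed_sensitivity": self.detailed_sensitivity.to_dict(),
            "correlations": {
                k: {"statistic": v[0], "pvalue": v[1]}
                for k, v in self.correlations.items()
            },
        }


def evaluate(
    predictions: pd.DataFrame,
    manifest: pd.DataFrame,
    h: LabelHierarchy,
    topk: Sequence[int] = (1, 2),
    ece_bins: int = 10,
    acute_leukemia_class: str = "acute leukemia",
) -> EvaluationReport:
    """Assemble the full evaluation report.

    ``predictions`` must carry patient_id, per-class probability columns
    named ``p_<coarse class>`` and predicted_hb; rows are matched to the
    manifest by patient_id.
    """
    prob_cols = [f"p_{c}" for c in h.coarse_classes]
    missing = [c for c in prob_cols + ["patient_id"] if c not in predictions.columns]
    if missing:
        raise ValueError(f"predictions table missing columns {missing}")
    merged = manifest.merge(predictions, on="patient_id", how="inner", validate="1:1")
    if len(merged) != len(manifest):
        raise ValueError("predictions do not cover every manifest patient")
    probs = merged[prob_cols].to_numpy(dtype=float)
    truth_coarse = list(merged["coarse_class"])
    truth_idx = np.array([h.class_index(c) for c in truth_coarse])
    pred_idx = probs.argmax(axis=1)
    pred_coarse = [h.coarse_classes[i] for i in pred_idx]
    cm, rates = confusion_and_rates(truth_coarse, pred_coarse, h.coarse_classes)
    det_cm, det_sens = detailed_confusion(
        list(merged["detailed_class"]), pred_coarse, h
    )
    mal_scores = [malignancy_probability(p, h) for p in probs]
    is_mal = [bool(h.malignant_flags[c]) for c in truth_coarse]
    hb_r = hb_mae = None
    if "predicted_hb" in merged.columns and "hemoglobin" in merged.columns:
        hb_r, hb_mae = hemoglobin_agreement(
            merged["predicted_hb"], merged["hemoglobin"]
        )
    correlations: dict[str, tuple[float, float]] = {}
    if "blast_ratio" in merged.columns:
        al_col = f"p_{acute_leukemia_class}"
        correlations["acute_leukemia_prob_vs_blast_ratio"] = rank_correlation(
            merged[al_col], merged["blast_ratio"]
        )
    if "lymphocyte_ratio" in merged.columns and "p_lymphoma" in predictions.columns:
        correlations["lymphoma_prob_vs_lymphocyte_ratio"] = rank_correlation(
            merged["p_lymphoma"], merged["lymphocyte_ratio"]
        )
    return EvaluationReport(
        coarse_confusion=cm,
        coarse_rates=rates,
        detailed_confusion_matrix=det_cm,
        detailed_sensitivity=det_sens,
        accuracy=float((pred_idx == truth_idx).mean()),
        topk={k: topk_accuracy(probs, truth_idx, k) for k in topk},
        auroc_malignant=auroc(mal_scores, is_mal),
        ece=expected_calibration_error(probs, truth_idx, ece_bins),
        hb_pearson=hb_r,
        hb_mae=hb_mae,
        correlations=correlations,
    )
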