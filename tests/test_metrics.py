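"""Triage and evaluation metrics, each cross-checked against an
independent brute-force oracle on small random instances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemomil as hm
from hemomil.simulate import RELEASED_TEST_SET_COUNTS

RNG = np.random.default_rng(123)


def random_simplex(n_rows, n_cols, rng):
    x = rng.gamma(1.0, size=(n_rows, n_cols))
    return x / x.sum(axis=1, keepdims=True)


# -- malignancy probability and triage ------------------------------------


@given(st.lists(st.floats(0.01, 10.0), min_size=8, max_size=8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_malignancy_identity(weights):
    """P(malignant) + P(reactive) + P(healthy) = 1 for any simplex point."""
    h = hm.default_hierarchy()
    p = np.array(weights) / np.sum(weights)
    mp = hm.malignancy_probability(p, h)
    benign = (
        p[h.class_index("reactive changes")] + p[h.class_index("healthy")]
    )
    assert mp + benign == pytest.approx(1.0, abs=1e-9)


def test_malignancy_probability_cases(hierarchy):
    assert hm.malignancy_probability(np.full(8, 1 / 8), hierarchy) == pytest.approx(
        0.75, abs=1e-12
    )
    one_hot_healthy = np.eye(8)[hierarchy.class_index("healthy")]
    assert hm.malignancy_probability(one_hot_healthy, hierarchy) == 0.0
    one_hot_mds = np.eye(8)[hierarchy.class_index("MDS")]
    assert hm.malignancy_probability(one_hot_mds, hierarchy) == 1.0


def test_triage_strict_comparison(hierarchy):
    def vec(mal_prob):
        p = np.zeros(8)
        p[hierarchy.class_index("MDS")] = mal_prob
        p[hierarchy.class_index("healthy")] = 1 - mal_prob
        return p

    assert hm.triage(vec(0.51), hierarchy, 0.5).recommend_biopsy
    assert not hm.triage(vec(0.50), hierarchy, 0.5).recommend_biopsy
    assert hm.triage(vec(0.01), hierarchy, 0.0).recommend_biopsy


# -- clinical baseline ------------------------------------------------------


def test_clinical_baseline_fdr_from_released_counts(hierarchy):
    """42 reactive / (42 + 268 malignant) = 13.5% unnecessary aspirations."""
    fdr = hm.clinical_baseline_fdr(RELEASED_TEST_SET_COUNTS, hierarchy)
    assert fdr == pytest.approx(42 / 310, abs=1e-12)
    assert round(100 * fdr, 1) == 13.5


def test_clinical_baseline_fdr_edges(hierarchy):
    no_reactive = dict(RELEASED_TEST_SET_COUNTS, **{"reactive changes": 0})
    assert hm.clinical_baseline_fdr(no_reactive, hierarchy) == 0.0
    only_reactive = {"reactive changes": 10}
    assert hm.clinical_baseline_fdr(only_reactive, hierarchy) == 1.0


# -- threshold sweep --------------------------------------------------------


def test_threshold_sweep_matches_brute_force_recount(hierarchy):
    n = 200
    probs = random_simplex(n, 8, RNG)
    classes = [hierarchy.coarse_classes[i] for i in RNG.integers(0, 8, n)]
    grid = np.linspace(0, 1, 21)
    result = hm.threshold_sweep(probs, classes, hierarchy, grid)
    mal_flags = np.array([hierarchy.malignant_flags[c] for c in classes])
    scores = np.array([hm.malignancy_probability(p, hierarchy) for p in probs])
    for _, row in result.table.iterrows():
        t = row["threshold"]
        rec = [s > t for s in scores]
        tp = sum(r and m for r, m in zip(rec, mal_flags))
        fp = sum(r and not m for r, m in zip(rec, mal_flags))
        fn = sum((not r) and m for r, m in zip(rec, mal_flags))
        tn = sum((not r) and not m for r, m in zip(rec, mal_flags))
        assert row["n_recommended"] == tp + fp
        assert row["malignancy_sensitivity"] == pytest.approx(tp / (tp + fn), abs=1e-9)
        assert row["malignancy_specificity"] == pytest.approx(tn / (tn + fp), abs=1e-9)
        if tp + fp:
            assert row["aspiration_fdr"] == pytest.approx(fp / (tp + fp), abs=1e-9)
        al = [
            r for r, c in zip(rec, classes) if c == "acute leukemia"
        ]
        if al:
            assert row["acute_leukemia_sensitivity"] == pytest.approx(
                sum(al) / len(al), abs=1e-9
            )


def test_threshold_sweep_monotone_recommendations(hierarchy):
    probs = random_simplex(120, 8, RNG)
    classes = [hierarchy.coarse_classes[i] for i in RNG.integers(0, 8, 120)]
    result = hm.threshold_sweep(probs, classes, hierarchy)
    n_rec = result.table["n_recommended"].to_numpy()
    assert np.all(np.diff(n_rec) <= 0)
    al = result.table["acute_leukemia_sensitivity"].to_numpy()
    assert np.all(np.diff(al[~np.isnan(al)]) <= 0)


def test_threshold_sweep_reports_missing_al_sensitivity(hierarchy):
    probs = random_simplex(20, 8, RNG)
    classes = ["healthy"] * 20
    result = hm.threshold_sweep(probs, classes, hierarchy, [0.5])
    assert np.isnan(result.table["acute_leukemia_sensitivity"]).all()
    assert result.best_full_al_sensitivity_threshold is None


def test_threshold_sweep_perfect_separation(hierarchy):
    mal = np.eye(8)[hierarchy.class_index("MDS")]
    ben = np.eye(8)[hierarchy.class_index("healthy")]
    probs = [mal] * 5 + [ben] * 5
    classes = ["acute leukemia"] * 5 + ["healthy"] * 5
    result = hm.threshold_sweep(probs, classes, hierarchy)
    best = result.table[result.table["acute_leukemia_sensitivity"] >= 1.0]
    assert (best["aspiration_fdr"] == 0).any()


# -- confusion and rates ----------------------------------------------------


def test_confusion_hand_counted_toy():
    order = ["A", "B", "C"]
    truth = ["A", "A", "A", "B", "B", "C", "C", "C", "C", "C"]
    pred = ["A", "B", "A", "B", "B", "C", "C", "A", "C", "C"]
    cm, rates = hm.confusion_and_rates(truth, pred, order)
    assert cm.loc["A", "A"] == 2 and cm.loc["A", "B"] == 1
    assert cm.to_numpy().sum(axis=1).tolist() == [3, 2, 5]
    assert rates.loc["A", "sensitivity"] == pytest.approx(2 / 3)
    assert rates.loc["B", "precision"] == pytest.approx(2 / 3)
    assert rates.loc["C", "sensitivity"] == pytest.approx(4 / 5)


def test_confusion_single_class_predictor_precision_is_prior():
    order = ["A", "B"]
    truth = ["A"] * 7 + ["B"] * 3
    pred = ["A"] * 10
    _, rates = hm.confusion_and_rates(truth, pred, order)
    assert rates.loc["A", "precision"] == pytest.approx(0.7)
    assert np.isnan(rates.loc["B", "precision"])  # never predicted: missing


def test_perfect_predictions_identity_matrix():
    order = ["A", "B", "C"]
    truth = ["A", "B", "C", "C"]
    cm, rates = hm.confusion_and_rates(truth, truth, order)
    assert (np.diag(cm) == [1, 1, 2]).all()
    assert (rates["sensitivity"] == 1.0).all()


# -- top-k ------------------------------------------------------------------


def test_topk_matches_exhaustive_enumeration():
    probs = random_simplex(50, 8, RNG)
    truth = RNG.integers(0, 8, 50)
    for k in (1, 2, 3, 8):
        expected = 0
        for p, t in zip(probs, truth):
            order = sorted(range(8), key=lambda j: (-p[j], j))
            expected += t in order[:k]
        assert hm.topk_accuracy(probs, truth, k) == pytest.approx(
            expected / 50, abs=1e-9
        )


def test_topk_edge_cases():
    probs = random_simplex(30, 8, RNG)
    truth = RNG.integers(0, 8, 30)
    assert hm.topk_accuracy(probs, truth, 8) == 1.0
    acc = np.mean(probs.argmax(axis=1) == truth)
    assert hm.topk_accuracy(probs, truth, 1) == pytest.approx(acc)


def test_topk_tie_broken_by_class_order():
    p = np.array([[0.25, 0.25, 0.25, 0.25]])
    assert hm.topk_accuracy(p, [1], 2) == 1.0  # indices 0,1 win the tie
    assert hm.topk_accuracy(p, [2], 2) == 0.0


# -- ECE --------------------------------------------------------------------


def ece_oracle(probs, truth, n_bins):
    conf = probs.max(axis=1)
    pred = probs.argmax(axis=1)
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        members = [
            i for i, c in enumerate(conf) if (lo < c <= hi) or (b == 0 and c == 0)
        ]
        if not members:
            continue
        acc = np.mean([pred[i] == truth[i] for i in members])
        avg_conf = np.mean([conf[i] for i in members])
        total += len(members) / len(conf) * abs(acc - avg_conf)
    return total


def test_ece_matches_brute_force():
    probs = random_simplex(50, 8, RNG)
    truth = RNG.integers(0, 8, 50)
    for bins in (1, 5, 10, 15):
        assert hm.expected_calibration_error(probs, truth, bins) == pytest.approx(
            ece_oracle(probs, truth, bins), abs=1e-9
        )


def test_ece_perfectly_calibrated_cases():
    # one-hot and always correct
    probs = np.eye(8)[np.arange(8)]
    assert hm.expected_calibration_error(probs, np.arange(8)) == pytest.approx(
        0.0, abs=1e-12
    )
    # confidence 0.9, 90% correct
    p = np.zeros((10, 8))
    p[:, 0] = 0.9
    p[:, 1:] = 0.1 / 7
    truth = np.zeros(10, dtype=int)
    truth[0] = 1  # exactly one wrong
    assert hm.expected_calibration_error(p, truth) == pytest.approx(0.0, abs=1e-12)


# -- AUROC ------------------------------------------------------------------


def auroc_oracle(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auroc_matches_all_pairs_oracle():
    scores = RNG.choice(np.linspace(0, 1, 9), size=20)  # forces ties
    truth = RNG.random(20) > 0.5
    if truth.all() or not truth.any():
        truth[0] = ~truth[0]
    assert hm.auroc(scores, truth) == pytest.approx(
        auroc_oracle(scores, truth), abs=1e-9
    )


def test_auroc_edge_cases():
    assert hm.auroc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0
    assert hm.auroc([0.5] * 6, [True, False] * 3) == 0.5
    with pytest.raises(ValueError):
        hm.auroc([0.1, 0.2], [True, True])


# -- agreement metrics ------------------------------------------------------


def test_agreement_closed_forms():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r, mae = hm.hemoglobin_agreement(x, x)
    assert r == pytest.approx(1.0) and mae == 0.0
    r, _ = hm.hemoglobin_agreement(x, -x)
    assert r == pytest.approx(-1.0)


def test_agreement_matches_direct_formula():
    x = RNG.normal(10, 2, size=10)
    y = x + RNG.normal(0, 1, size=10)
    r, mae = hm.hemoglobin_agreement(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(r_direct, abs=1e-12)
    assert mae == pytest.approx(np.abs(x - y).mean(), abs=1e-12)


def test_rank_correlation_monotone():
    x = RNG.normal(size=15)
    rho, p = hm.rank_correlation(x, np.exp(x))  # monotone map
    assert rho == pytest.approx(1.0)
    assert p < 1e-6


def test_agreement_requires_three_pairs():
    with pytest.raises(ValueError):
        hm.hemoglobin_agreement([1.0, 2.0], [1.0, 2.0])
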