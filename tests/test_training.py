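import numpy as np
import pytest

import hemomil as hm


def test_make_folds_balanced_per_class():
    # 40 patients, 8 classes x 5, k=5 -> exactly one per class per fold
    import pandas as pd

    h = hm.default_hierarchy()
    rows = [
        {"patient_id": f"P{i}", "coarse_class": h.coarse_classes[i % 8]}
        for i in range(40)
    ]
    manifest = pd.DataFrame(rows)
    plan = hm.make_folds(manifest, 5, seed=0)
    for fold in range(5):
        members = [p for p, f in plan.assignments.items() if f == fold]
        classes = [manifest.set_index("patient_id").loc[p, "coarse_class"] for p in members]
        assert sorted(classes) == sorted(h.coarse_classes)


def _uniform_manifest(n=72):
    import pandas as pd

    h = hm.default_hierarchy()
    rng = np.random.default_rng(0)
    classes = rng.permutation([h.coarse_classes[i % 8] for i in range(n)])
    return pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(n)], "coarse_class": classes}
    )


def test_make_folds_deterministic():
    manifest = _uniform_manifest()
    p1 = hm.make_folds(manifest, 5, seed=4)
    p2 = hm.make_folds(manifest, 5, seed=4)
    assert p1.assignments == p2.assignments


def test_make_folds_proportionality_bound():
    manifest = _uniform_manifest(67)
    plan = hm.make_folds(manifest, 5, seed=4)
    fold_ids = manifest["patient_id"].map(plan.assignments)
    for cls, group in manifest.groupby("coarse_class"):
        counts = fold_ids[group.index].value_counts().reindex(range(5), fill_value=0)
        assert counts.max() - counts.min() <= 1


def test_make_folds_rejects_sparse_class():
    import pandas as pd

    manifest = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(8)],
            "coarse_class": ["MDS"] * 5 + ["healthy"] * 3,
        }
    )
    with pytest.raises(ValueError, match="healthy"):
        hm.make_folds(manifest, 5, seed=0)


def test_k1_degenerate_training_smoke(tiny_ensemble):
    assert len(tiny_ensemble.members) == 1
    assert tiny_ensemble.fold_plan is None
    # training actually learned something beyond chance on train data
    final = [r for r in tiny_ensemble.logs if r["epoch"] == max(x["epoch"] for x in tiny_ensemble.logs)]
    assert final[0]["train_acc"] > 0.3


def test_no_leakage_between_folds(positive_control):
    ensemble = positive_control["ensemble"]
    plan = ensemble.fold_plan
    test_ids = set(positive_control["test_manifest"]["patient_id"])
    train_ids = set(plan.assignments)
    assert test_ids & train_ids == set()
    # each fold's validation ids disjoint from its training ids by construction
    folds = {f: {p for p, g in plan.assignments.items() if g == f} for f in range(plan.k)}
    for f in folds:
        rest = set().union(*(folds[g] for g in folds if g != f))
        assert folds[f] & rest == set()


def test_ensemble_of_identical_members_equals_single(tiny_ensemble, tiny_cohort):
    _, bags = tiny_cohort
    member = tiny_ensemble.members[0]
    doubled = hm.Ensemble(
        members=[member, member],
        class_order=tiny_ensemble.class_order,
        config=tiny_ensemble.config,
    )
    p1 = member.predict_bag(bags[0])
    p2 = hm.ensemble_predict(doubled, bags[0])
    np.testing.assert_allclose(p1.class_probabilities, p2.class_probabilities, atol=1e-12)
    assert p1.hemoglobin_predicted == pytest.approx(p2.hemoglobin_predicted)


def test_ensemble_mean_stays_on_simplex(positive_control):
    bag = positive_control["test_bags"][0]
    pred = hm.ensemble_predict(positive_control["ensemble"], bag)
    assert pred.class_probabilities.sum() == pytest.approx(1.0, abs=1e-9)
    assert pred.attention_weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_ensembling_no_worse_than_best_member_minus_margin(positive_control):
    """Probability-averaged ensemble top-1 accuracy trails the best single
    member by at most 2 points on the positive control."""
    h = hm.default_hierarchy()
    ensemble = positive_control["ensemble"]
    test_man = positive_control["test_manifest"]
    bags = positive_control["test_bags"]
    truth = np.array([h.class_index(c) for c in test_man["coarse_class"]])
    member_accs = []
    for m in ensemble.members:
        pred = np.array(
            [m.predict_bag(b).class_probabilities.argmax() for b in bags]
        )
        member_accs.append((pred == truth).mean())
    assert positive_control["accuracy"] >= max(member_accs) - 0.02


def test_predict_table_schema(tiny_ensemble, tiny_cohort, hierarchy):
    _, bags = tiny_cohort
    table = hm.predict_table(tiny_ensemble, bags[:5], hierarchy)
    assert list(table.columns) == (
        ["patient_id"] + [f"p_{c}" for c in hierarchy.coarse_classes] + ["predicted_hb"]
    )
    probs = table.filter(like="p_").to_numpy()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
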