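import numpy as np
import pytest

import hemomil as hm
from hemomil.model import load_checkpoint, save_checkpoint

RNG = np.random.default_rng(7)


@pytest.fixture(scope="module")
def config():
    return hm.ModelConfig(
        embedding_dim=16, bag_size=40, latent_dim=32, n_heads=4, n_layers=2, seed=5
    )


@pytest.fixture(scope="module")
def model(config):
    return hm.build_model(config)


def _bag(n, dim=16, seed=0):
    return hm.CellBag("P", np.random.default_rng(seed).normal(size=(n, dim)))


def test_config_divisibility_enforced():
    with pytest.raises(ValueError, match="divisible"):
        hm.ModelConfig(latent_dim=65, n_heads=4)


def test_config_dropout_bounds():
    with pytest.raises(ValueError):
        hm.ModelConfig(dropout=1.0)


def test_same_seed_identical_parameters(config):
    m1, m2 = hm.build_model(config), hm.build_model(config)
    for p, q in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(p.data, q.data)


def test_prediction_simplexes(model):
    pred = model.predict_bag(_bag(30))
    assert pred.class_probabilities.sum() == pytest.approx(1.0, abs=1e-6)
    assert pred.attention_weights.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(pred.class_probabilities >= 0)
    assert np.all(pred.attention_weights >= 0)
    assert pred.patient_vector.shape == (32,)


def test_permutation_invariance_and_attention_equivariance(model):
    bag = _bag(25, seed=1)
    perm = RNG.permutation(25)
    shuffled = hm.CellBag("P", bag.embeddings[perm])
    p0 = model.predict_bag(bag)
    p1 = model.predict_bag(shuffled)
    np.testing.assert_allclose(
        p0.class_probabilities, p1.class_probabilities, atol=1e-5
    )
    assert p0.hemoglobin_predicted == pytest.approx(
        p1.hemoglobin_predicted, abs=1e-5
    )
    np.testing.assert_allclose(
        p0.attention_weights[perm], p1.attention_weights, atol=1e-5
    )


def test_singleton_bag_attention_is_one(model):
    pred = model.predict_bag(_bag(1))
    np.testing.assert_allclose(pred.attention_weights, [1.0], atol=1e-12)


@pytest.mark.parametrize("n_cells", [1, 2, 39, 40, 41, 120])
def test_variable_bag_sizes_accepted(model, n_cells):
    pred = model.predict_bag(_bag(n_cells, seed=n_cells))
    assert pred.attention_weights.shape == (n_cells,)


def test_dimension_mismatch_rejected(model):
    with pytest.raises(ValueError):
        model.predict_bag(_bag(10, dim=8))


def test_loss_closed_forms(config):
    perfect = hm.BagPrediction(
        class_probabilities=np.eye(8)[2],
        hemoglobin_predicted=12.0,
        patient_vector=np.zeros(32),
        attention_weights=np.ones(4) / 4,
    )
    total, ce, reg = hm.loss(perfect, 2, 12.0, config)
    assert total == 0.0 and ce == 0.0 and reg == 0.0

    uniform = hm.BagPrediction(
        class_probabilities=np.full(8, 1 / 8),
        hemoglobin_predicted=10.0,
        patient_vector=np.zeros(32),
        attention_weights=np.ones(4) / 4,
    )
    total, ce, reg = hm.loss(uniform, 5, 10.0, config)
    assert ce == pytest.approx(np.log(8), abs=1e-12)
    assert total == pytest.approx(np.log(8), abs=1e-12)

    from dataclasses import replace

    no_hb = replace(config, hb_loss_weight=0.0)
    total, ce, reg = hm.loss(uniform, 5, 99.0, no_hb)
    assert total == ce


def test_subsample_bag_behavior():
    big = _bag(800, seed=2)
    sub = hm.subsample_bag(big, 500, seed=3)
    assert sub.n_cells == 500
    # all rows come from the original, no repeats
    seen = {tuple(r) for r in big.embeddings}
    assert all(tuple(r) in seen for r in sub.embeddings)
    assert len({tuple(r) for r in sub.embeddings}) == 500

    small = _bag(300, seed=4)
    assert hm.subsample_bag(small, 500, seed=5) is small

    s1 = hm.subsample_bag(big, 100, seed=6)
    s2 = hm.subsample_bag(big, 100, seed=6)
    np.testing.assert_array_equal(s1.embeddings, s2.embeddings)


def test_single_gradient_step_decreases_batch_loss(config):
    from hemomil.autograd import Adam, Tensor

    model = hm.build_model(config)
    x = RNG.normal(size=(8, 20, 16))
    y = RNG.integers(0, 8, size=8)
    hb = RNG.normal(size=8)

    def batch_loss():
        logits, hb_out, _, _ = model.forward(x)
        resid = hb_out - Tensor(hb)
        return logits.cross_entropy(y) + config.hb_loss_weight * (resid * resid).mean()

    opt = Adam(model.parameters(), lr=1e-3)
    before = float(batch_loss().data)
    loss = batch_loss()
    loss.backward()
    opt.step()
    after = float(batch_loss().data)
    assert after < before


def test_checkpoint_roundtrip(tmp_path, config, model, hierarchy):
    model.hb_mean, model.hb_scale = 11.5, 2.25
    path = tmp_path / "m.npz"
    save_checkpoint(model, path, hierarchy.coarse_classes)
    loaded = load_checkpoint(path, hierarchy.coarse_classes)
    bag = _bag(12, seed=9)
    p0, p1 = model.predict_bag(bag), loaded.predict_bag(bag)
    np.testing.assert_array_equal(p0.class_probabilities, p1.class_probabilities)
    assert p0.hemoglobin_predicted == p1.hemoglobin_predicted


def test_checkpoint_refuses_wrong_class_order(tmp_path, model, hierarchy):
    path = tmp_path / "m.npz"
    save_checkpoint(model, path, hierarchy.coarse_classes)
    wrong = tuple(reversed(hierarchy.coarse_classes))
    with pytest.raises(ValueError, match="class order"):
        load_checkpoint(path, wrong)
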