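import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripletknn.embedding import (
    EmbeddingModel,
    TrainConfig,
    calibrate_init_scale,
    class_distance_ratio,
    embed,
    init_model,
    mine_all_valid,
    mine_semi_hard,
    pairwise_distances,
    train_embedding,
    triplet_loss,
)

from .oracles import semi_hard_triplets


# ---------------------------------------------------------------- loss

@pytest.mark.parametrize(
    "d_ap, d_an, m, expected",
    [
        (0.0, 0.2, 0.2, 0.0),     # hinge boundary
        (2.0, 1.0, 0.5, 1.5),     # direct substitution
        (1.0, 5.0, 0.5, 0.0),     # inactive hinge
        (0.3, 0.3, 0.1, 0.1),     # equal distances -> margin
    ],
)
def test_triplet_loss_values(d_ap, d_an, m, expected):
    assert triplet_loss(d_ap, d_an, m) == pytest.approx(expected)


@given(
    d_ap=st.floats(0, 100, allow_nan=False),
    gap=st.floats(0, 100, allow_nan=False),
    m=st.floats(0.01, 10, allow_nan=False),
)
@settings(max_examples=200, derandomize=True)
def test_triplet_loss_hinge_properties(d_ap, gap, m):
    # inactive whenever the negative clears the positive by at least m
    # (up to the rounding of d_ap + m + gap itself)
    assert triplet_loss(d_ap, d_ap + m + gap, m) <= 1e-12 * max(1.0, d_ap + m)
    # always nonnegative, and bounded by d_ap + m
    val = triplet_loss(d_ap, gap, m)
    assert 0.0 <= val <= d_ap + m


def test_triplet_loss_rejects_bad_inputs():
    with pytest.raises(ValueError):
        triplet_loss(-0.1, 1.0, 0.2)
    with pytest.raises(ValueError):
        triplet_loss(0.1, 1.0, 0.0)
    with pytest.raises(ValueError):
        triplet_loss(float("nan"), 1.0, 0.2)


# ---------------------------------------------------------------- mining

def test_semi_hard_mining_one_dimensional_example():
    """Class-0 points {0.0, 0.1}, class-1 points {0.15, 5.0}, m=0.5: for
    anchor 0.0 / positive 0.1 only the negative at 0.15 satisfies
    0.1 < d < 0.6; the far point at 5.0 never qualifies."""
    X = np.array([[0.0], [0.1], [0.15], [5.0]])
    y = [0, 0, 1, 1]
    mined = {(t.anchor, t.positive, t.negative) for t in mine_semi_hard(X, y, 0.5)}
    assert (0, 1, 2) in mined
    assert all(t[2] != 3 for t in mined)
    # exact expected set from exhaustive reasoning
    assert mined == semi_hard_triplets(X, y, 0.5, "euclidean")


def test_no_qualifying_negative_yields_empty_list():
    X = np.array([[0.0], [0.1], [50.0], [60.0]])
    assert mine_semi_hard(X, [0, 0, 1, 1], m=0.5) == []


def test_single_class_batch_warns_and_returns_empty(caplog):
    X = np.random.default_rng(0).normal(size=(4, 3))
    with caplog.at_level("WARNING"):
        out = mine_semi_hard(X, [1, 1, 1, 1], m=0.2)
    assert out == []
    assert "single-class" in caplog.text


@pytest.mark.parametrize("distance", ["euclidean", "cosine"])
@pytest.mark.parametrize("m", [0.1, 0.2, 0.5])
def test_mining_matches_exhaustive_oracle(distance, m, rng):
    for _ in range(50):
        n = int(rng.integers(4, 17))
        X = rng.normal(size=(n, int(rng.integers(2, 6))))
        y = rng.integers(0, 2, size=n)
        mined = {(t.anchor, t.positive, t.negative)
                 for t in mine_semi_hard(X, y, m, distance)}
        assert mined == semi_hard_triplets(X, y, m, distance)


def test_all_valid_miner_returns_active_triplets(rng):
    X = rng.normal(size=(8, 3))
    y = [0, 0, 0, 0, 1, 1, 1, 1]
    D = pairwise_distances(X, "euclidean")
    got = mine_all_valid(X, y, m=0.5)
    for t in got:
        assert y[t.anchor] == y[t.positive] != y[t.negative]
        assert D[t.anchor, t.positive] - D[t.anchor, t.negative] + 0.5 > 0


# ---------------------------------------------------------------- embed

def test_identity_model_is_identity(rng):
    model = EmbeddingModel(np.eye(5), margin=0.2)
    X = rng.normal(size=(7, 5))
    np.testing.assert_allclose(embed(model, X), X)


def test_embed_empty_and_dimension_checks(rng):
    model = init_model(8, 4, seed=0)
    assert embed(model, np.empty((0, 8))).shape == (0, 4)
    with pytest.raises(ValueError, match="features must be"):
        embed(model, rng.normal(size=(3, 5)))


def test_embed_is_linear_when_unnormalized(rng):
    model = init_model(6, 3, seed=1)
    X = rng.normal(size=(4, 6))
    np.testing.assert_allclose(embed(model, 2.5 * X), 2.5 * embed(model, X))
    np.testing.assert_allclose(
        embed(model, X[:2] + X[2:]), embed(model, X[:2]) + embed(model, X[2:])
    )


def test_normalized_embeddings_have_unit_norm(rng):
    model = init_model(6, 3, seed=1, normalized=True)
    E = embed(model, rng.normal(size=(5, 6)))
    np.testing.assert_allclose(np.linalg.norm(E, axis=1), 1.0)


# ---------------------------------------------------------------- training

def _separable_corpus(seed, n=60, dim=32, sep=10.0):
    rng = np.random.default_rng(seed)
    axis = np.zeros(dim)
    axis[0] = 1.0
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.normal(size=(n, dim)) + np.where(y[:, None] == 0, sep / 2, -sep / 2) * axis
    return X, ["benign" if v == 0 else "malignant" for v in y]


def test_zero_epochs_returns_initialization(rng):
    X, y = _separable_corpus(0)
    model0 = init_model(32, 8, seed=0)
    model, history = train_embedding(X, y, TrainConfig(epochs=0, seed=0), model0)
    np.testing.assert_array_equal(model.weight, model0.weight)
    assert history == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_training_decreases_loss_on_separable_data(seed):
    X, y = _separable_corpus(seed, sep=10.0)
    model0 = calibrate_init_scale(init_model(32, 8, seed=seed, margin=0.2), X)
    model, history = train_embedding(X, y, TrainConfig(seed=seed), model0)
    mined = [h for h in history if h.n_triplets > 0]
    assert mined[-1].mean_loss < mined[0].mean_loss


def test_mined_losses_bounded_by_margin():
    """Semi-hard mining implies every mined triplet's loss is in (0, m]."""
    X, y = _separable_corpus(3, sep=5.0)
    m = 0.3
    model0 = calibrate_init_scale(init_model(32, 8, seed=3, margin=m), X)
    _, history = train_embedding(X, y, TrainConfig(seed=3), model0)
    for h in history:
        if h.n_triplets:
            assert 0.0 < h.min_loss <= h.max_loss <= m + 1e-9


def test_training_is_deterministic():
    X, y = _separable_corpus(4)
    model0 = calibrate_init_scale(init_model(32, 8, seed=4), X)
    m1, h1 = train_embedding(X, y, TrainConfig(epochs=5, seed=4), model0)
    m2, h2 = train_embedding(X, y, TrainConfig(epochs=5, seed=4), model0)
    np.testing.assert_array_equal(m1.weight, m2.weight)
    assert h1 == h2


def test_training_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(10, 4))
    with pytest.raises(ValueError, match="two classes"):
        train_embedding(X, ["benign"] * 10, TrainConfig(), init_model(4, 2))


def test_training_improves_class_separation_most_seeds():
    """With separation >= 5x noise, the inter/intra distance ratio after
    training should be at least the untrained ratio in >= 8/10 seeds."""
    wins = 0
    for seed in range(10):
        X, y = _separable_corpus(seed, n=48, dim=32, sep=5.0)
        model0 = calibrate_init_scale(init_model(32, 8, seed=seed), X)
        model, _ = train_embedding(X, y, TrainConfig(epochs=10, seed=seed), model0)
        before = class_distance_ratio(embed(model0, X), y)
        after = class_distance_ratio(embed(model, X), y)
        wins += after >= before
    assert wins >= 8


def test_cosine_distance_training_runs():
    # moderate separation: with sep=10 cosine gaps exceed the margin band
    # everywhere and nothing is semi-hard, so use overlapping clouds
    X, y = _separable_corpus(6, n=40, dim=16, sep=1.0)
    model0 = init_model(16, 8, seed=6, distance="cosine", margin=0.2)
    model, history = train_embedding(X, y, TrainConfig(epochs=5, seed=6), model0)
    assert any(h.n_triplets > 0 for h in history)
    assert np.all(np.isfinite(model.weight))


# ---------------------------------------------------------------- model io

def test_model_save_load_roundtrip(tmp_path):
    model = init_model(12, 4, seed=2, distance="cosine", margin=0.7, normalized=True)
    path = tmp_path / "model.npz"
    model.save(path)
    back = EmbeddingModel.load(path)
    np.testing.assert_array_equal(back.weight, model.weight)
    assert (back.distance, back.margin, back.normalized) == ("cosine", 0.7, True)


def test_calibration_targets_margin_scale(rng):
    X = rng.normal(size=(100, 32)) * 50.0
    model = init_model(32, 8, seed=0, margin=0.2)
    cal = calibrate_init_scale(model, X)
    E = embed(cal, X)
    iu = np.triu_indices(100, 1)
    med = np.median(pairwise_distances(E, "euclidean")[iu])
    assert med == pytest.approx(2 * 0.2, rel=0.15)
    # scale-invariant settings are untouched
    cos = init_model(32, 8, seed=0, distance="cosine")
    np.testing.assert_array_equal(calibrate_init_scale(cos, X).weight, cos.weight)
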