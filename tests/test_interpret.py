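import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from tripletknn.interpret import (
    ExplanationBundle,
    combine,
    explain_prediction,
    fit_projection,
    foreign_separation,
    patient_view,
    project,
)
from tripletknn.knn import knn_predict


def _two_clusters(rng, n=40, dim=8, sep=12.0):
    X = rng.normal(size=(n, dim))
    X[: n // 2, 0] += sep / 2
    X[n // 2:, 0] -= sep / 2
    labels = ["benign"] * (n // 2) + ["malignant"] * (n // 2)
    return X, labels


def test_projection_determinism_and_shape(rng):
    X, _ = _two_clusters(rng)
    p1 = fit_projection(X, method="pca", seed=0)
    p2 = fit_projection(X, method="pca", seed=0)
    c1, c2 = p1.transform(X), p2.transform(X)
    np.testing.assert_array_equal(c1, c2)
    assert c1.shape == (40, 2)
    assert np.all(np.isfinite(c1))


def test_projection_requires_enough_points_and_right_dim(rng):
    X, _ = _two_clusters(rng)
    with pytest.raises(ValueError, match=">= 10"):
        fit_projection(X[:5])
    proj = fit_projection(X)
    with pytest.raises(ValueError, match="expects"):
        proj.transform(rng.normal(size=(3, 5)))


def test_projector_is_fit_on_train_only(rng):
    """Transforming extra (test) points must not perturb train coordinates."""
    X, _ = _two_clusters(rng)
    Xtest = rng.normal(size=(15, 8))
    proj = fit_projection(X, seed=0)
    before = proj.transform(X)
    proj.transform(Xtest)  # out-of-sample use
    np.testing.assert_array_equal(proj.transform(X), before)
    # and refitting on the same train data reproduces them exactly
    np.testing.assert_array_equal(fit_projection(X, seed=0).transform(X), before)


def test_separated_classes_stay_separated_in_2d(rng):
    X, labels = _two_clusters(rng, n=60)
    proj = fit_projection(X, seed=0)
    coords = proj.transform(X)
    assert silhouette_score(coords, labels) > 0.5


def test_project_tags_roles_and_checks_lengths(rng):
    X, labels = _two_clusters(rng, n=20)
    proj = fit_projection(X)
    res = project(proj, X, "train", [f"i{j}" for j in range(20)], labels,
                  [f"p{j % 4}" for j in range(20)])
    assert set(res.frame["role"]) == {"train"}
    assert len(res) == 20
    with pytest.raises(ValueError, match="role"):
        project(proj, X, "validation", [f"i{j}" for j in range(20)])
    with pytest.raises(ValueError, match="image_id"):
        project(proj, X, "test", ["only-one"])


def test_projection_roundtrip_through_csv(tmp_path, rng):
    X, labels = _two_clusters(rng, n=20)
    proj = fit_projection(X)
    res = project(proj, X, "train", [f"i{j}" for j in range(20)], labels)
    path = tmp_path / "proj.csv"
    res.write(path)
    from tripletknn.interpret import ProjectionResult

    back = ProjectionResult.read(path)
    assert list(back.frame["image_id"]) == list(res.frame["image_id"])
    np.testing.assert_allclose(back.coords, res.coords)


def test_umap_projector_contract(rng):
    """The UMAP implementation satisfies the same fitted-projector contract."""
    X, _ = _two_clusters(rng, n=30)
    p1 = fit_projection(X, method="umap", seed=42, n_neighbors=5)
    c1 = p1.transform(X)
    assert c1.shape == (30, 2) and np.all(np.isfinite(c1))
    c2 = fit_projection(X, method="umap", seed=42, n_neighbors=5).transform(X)
    np.testing.assert_allclose(c1, c2)


def test_patient_view_detects_straddlers(rng):
    X, labels = _two_clusters(rng, n=40)
    proj = fit_projection(X, seed=0)
    ids = [f"i{j}" for j in range(40)]
    patients = ["pure_b"] * 20 + ["pure_m"] * 20
    train = project(proj, X, "train", ids, labels, patients)
    # a synthetic straddler: test points on both sides of the boundary
    Xs = np.vstack([X[:3], X[-3:]])
    test = project(proj, Xs, "test", [f"s{j}" for j in range(6)],
                   ["benign"] * 6, ["straddler"] * 6)
    full = combine(train, test)
    view = patient_view(full, "straddler")
    assert view.straddles
    assert view.n_near_benign == 3 and view.n_near_malignant == 3
    pure = patient_view(full, "pure_b")
    assert not pure.straddles and pure.n_near_malignant == 0
    with pytest.raises(KeyError, match="ghost"):
        patient_view(full, "ghost")


def test_explanations_mirror_the_prediction(rng):
    X, labels = _two_clusters(rng, n=30)
    Xte = rng.normal(size=(5, 8))
    pset = knn_predict(X, labels, Xte, k=3,
                       train_ids=[f"t{j}" for j in range(30)],
                       test_ids=[f"q{j}" for j in range(5)])
    for qid in pset.image_ids:
        bundle = explain_prediction(pset, qid)
        assert len(bundle.neighbor_ids) == 3
        assert list(bundle.distances) == sorted(bundle.distances)
        # the neighbour majority is the prediction, by definition of k-NN
        n_benign = sum(lb == "benign" for lb in bundle.labels)
        expect = "benign" if 2 * n_benign > 3 else "malignant"
        assert bundle.predicted_label == expect
    with pytest.raises(KeyError):
        explain_prediction(pset, "nope")


def test_explanation_bundle_roundtrip(tmp_path, rng):
    X, labels = _two_clusters(rng, n=20)
    pset = knn_predict(X, labels, rng.normal(size=(1, 8)), k=3)
    bundle = explain_prediction(pset, pset.image_ids[0],
                                thumbnails={p: f"/thumbs/{p}.png"
                                            for p in pset.predictions[0].evidence.neighbor_ids})
    path = tmp_path / "bundle.csv"
    bundle.write(path)
    back = ExplanationBundle.read(path)
    assert back.neighbor_ids == bundle.neighbor_ids
    np.testing.assert_allclose(back.distances, bundle.distances)
    assert back.thumbnail_paths == bundle.thumbnail_paths


def test_foreign_separation_fraction(rng):
    train = rng.normal(size=(50, 2))
    far = rng.normal(size=(30, 2)) + 100.0
    near = rng.normal(size=(30, 2))
    assert foreign_separation(train, far) == 1.0
    # same-distribution points are *not* flagged as a separated cloud: a
    # fresh point's nearest-train distance straddles the train median, so
    # the fraction hovers near 0.5 rather than approaching 1
    assert foreign_separation(train, near) < 0.8
    with pytest.raises(ValueError):
        foreign_separation(train[:1], far)


def test_plot_projection_writes_figure(tmp_path, rng):
    X, labels = _two_clusters(rng, n=20)
    proj = fit_projection(X)
    res = project(proj, X, "train", [f"i{j}" for j in range(20)], labels)
    from tripletknn.interpret import plot_projection

    out = tmp_path / "proj.png"
    plot_projection(res, out)
    assert out.stat().st_size > 0
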