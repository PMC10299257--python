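"""Metrics, validation splitting, selection, and embeddings."""

import numpy as np
import pandas as pd
import pytest

from aldhdrivers.models import (
    ModelSpec,
    ValidationScheme,
    auroc,
    confusion,
    cross_validate,
    embed_2d,
    feature_importance,
    greedy_forward_select,
    make_splits,
    metrics_from_counts,
    pca,
)


def test_confusion_hand_tally():
    y_true = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
    y_pred = [1, 0, 1, 0, 1, 0, 1, 0, 0, 0]
    c = confusion(y_true, y_pred)
    assert (c.tp, c.fp, c.tn, c.fn) == (3, 1, 4, 2)
    perfect = confusion([0, 1], [0, 1])
    assert perfect.fp == perfect.fn == 0
    inverted = confusion([0, 1], [1, 0])
    assert inverted.tp == inverted.tn == 0
    with pytest.raises(ValueError):
        confusion([0, 1, 2], [0, 1, 2])


def test_metrics_worked_example():
    from aldhdrivers.models import ConfusionCounts

    m = metrics_from_counts(ConfusionCounts(tp=33, fp=7, tn=61, fn=7))
    assert m.mcc == pytest.approx(1964 / 2720, abs=1e-9)
    assert m.recall == pytest.approx(0.825)
    assert m.precision == pytest.approx(0.825)
    perfect = metrics_from_counts(
        ConfusionCounts(5, 0, 5, 0), y_true=[1] * 5 + [0] * 5,
        scores=[0.9] * 5 + [0.1] * 5,
    )
    assert all(v == 1.0 for v in perfect.as_dict().values())


def test_mcc_equals_pearson_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(10, 60))
        y_true = rng.integers(0, 2, size=n)
        y_pred = rng.integers(0, 2, size=n)
        if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
            continue
        m = metrics_from_counts(confusion(y_true, y_pred))
        pearson = np.corrcoef(y_true, y_pred)[0, 1]
        assert m.mcc == pytest.approx(pearson, abs=1e-9)


def test_auroc_rank_formula_equals_pair_probability():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(10, 100))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        s = np.round(rng.normal(size=n), 1)  # rounding induces ties
        pos, neg = s[y == 1], s[y == 0]
        brute = np.mean([
            1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
        ])
        assert auroc(y, s) == pytest.approx(brute, abs=1e-12)
    assert auroc([0, 1, 0, 1], [0.5] * 4) == 0.5


def test_auroc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, size=80)
    s = rng.normal(size=80)
    assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_kcv_folds_partition_indices():
    labels = np.array([0, 1] * 10)
    scheme = ValidationScheme(kind="bootstrapped_kcv", k=10, seed=4)
    splits = make_splits(labels, None, scheme)
    assert len(splits) == 10
    all_test = np.sort(np.concatenate([te for _, te in splits]))
    assert np.array_equal(all_test, np.arange(20))
    for tr, te in splits:
        assert set(tr) & set(te) == set()


def test_jackknife_and_lopo_splits():
    labels = np.array([0, 1, 0, 1, 1])
    splits = make_splits(labels, None, ValidationScheme(kind="jackknife"))
    assert len(splits) == 5 and all(len(te) == 1 for _, te in splits)

    genes = np.array(["ALDH2"] * 3 + ["ALDH7A1"] * 9)
    labels = np.array([0, 1, 0] + [1, 0, 1, 0, 1, 0, 1, 0, 1])
    splits = make_splits(labels, genes, ValidationScheme(kind="lopo"))
    assert len(splits) == 2
    for tr, te in splits:
        assert set(genes[tr]) & set(genes[te]) == set()


def _separable_data(seed=0, n=100):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0, 1, size=(n // 2, 3)),
        rng.normal(6, 1, size=(n // 2, 3)),
    ])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    groups = np.array([f"g{i % 6}" for i in range(n)])
    return X, y, groups


@pytest.mark.parametrize("kind", ["bootstrapped_kcv", "jackknife", "lopo"])
def test_separable_data_near_perfect(kind):
    X, y, groups = _separable_data()
    scheme = ValidationScheme(kind=kind, repetitions=2, seed=0)
    spec = ModelSpec(n_estimators=50, seed=0)
    metrics, _ = cross_validate(spec, X, y, scheme, groups=groups)
    assert metrics.mcc >= 0.9


def test_cross_validate_deterministic_and_row_order_invariant():
    X, y, groups = _separable_data(3)
    scheme = ValidationScheme(kind="bootstrapped_kcv", repetitions=2, seed=5)
    spec = ModelSpec(n_estimators=30, seed=5)
    m1, _ = cross_validate(spec, X, y, scheme, groups=groups)
    m2, _ = cross_validate(spec, X, y, scheme, groups=groups)
    assert m1.as_dict() == m2.as_dict()
    # permute rows: stratified CV on the same seed gives the same pooled MCC
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(y))
    m3, _ = cross_validate(spec, X[perm], y[perm], scheme, groups=groups[perm])
    assert m3.mcc == pytest.approx(m1.mcc, abs=0.15)


def test_permuted_labels_give_null_mcc():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 4))
    mccs = []
    for rep in range(20):
        y = rng.permutation([0] * 30 + [1] * 30)
        scheme = ValidationScheme(kind="bootstrapped_kcv", k=5, repetitions=1, seed=rep)
        m, _ = cross_validate(ModelSpec(n_estimators=20, seed=rep), X, y, scheme)
        mccs.append(m.mcc)
    assert -0.15 <= np.mean(mccs) <= 0.15


def test_greedy_selection_finds_planted_feature():
    rng = np.random.default_rng(7)
    n = 80
    y = np.array([0] * 40 + [1] * 40)
    planted = y * 5.0 + rng.normal(0, 0.5, n)
    feats = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"noise_{i}" for i in range(10)])
    feats["planted"] = planted
    scheme = ValidationScheme(kind="bootstrapped_kcv", k=5, repetitions=1, seed=0)
    trace = greedy_forward_select(
        feats, y, ModelSpec(n_estimators=30, seed=0), scheme, max_features=3,
        epsilon=0.02,
    )
    assert trace.selected[0] == "planted"
    # objective non-decreasing along the trace
    objectives = [v for _, v in trace.steps]
    assert objectives == sorted(objectives)
    assert sum(trace.importances.values()) == pytest.approx(1.0, abs=1e-9)


def test_greedy_selection_max_features_and_all_constant():
    y = np.array([0, 1] * 10)
    feats = pd.DataFrame({"c1": np.ones(20), "c2": np.zeros(20)})
    trace = greedy_forward_select(
        feats, y, ModelSpec(n_estimators=10),
        ValidationScheme(kind="bootstrapped_kcv", k=2, repetitions=1),
    )
    assert trace.selected == [] and "all_constant" in trace.flags


def test_feature_importance_single_feature_model():
    from sklearn.ensemble import GradientBoostingClassifier

    rng = np.random.default_rng(8)
    X = rng.normal(size=(40, 1))
    y = (X[:, 0] > 0).astype(int)
    est = GradientBoostingClassifier(n_estimators=10, random_state=0).fit(X, y)
    imp = feature_importance(est, ["only"])
    assert imp == {"only": 1.0}
    with pytest.raises(ValueError):
        feature_importance(object(), ["x"])


def test_pca_matches_independent_eigensolution():
    X = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.1]])
    scores, loadings, explained = pca(X)
    # independent route: SVD of the centred matrix
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (len(X) - 1)
    assert explained[0] == pytest.approx(var[0] / var.sum(), abs=1e-9)
    assert np.allclose(np.abs(scores[:, 0]), np.abs(Xc @ vt[0]), atol=1e-9)
    # collinear data: first component explains ~everything
    line = np.outer(np.arange(10.0), [1.0, 2.0])
    _, _, ev = pca(line)
    assert ev[0] >= 0.999
    assert ev.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 4))
    _, l1, _ = pca(X, 2)
    _, l2, _ = pca(X.copy(), 2)
    assert np.allclose(l1, l2)
    for j in range(l1.shape[1]):
        assert l1[np.argmax(np.abs(l1[:, j])), j] > 0


def test_embed_pca_equals_first_two_components():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(20, 5))
    emb = embed_2d(X, method="pca", seed=0)
    scores, _, _ = pca(X, 2)
    assert np.allclose(emb, scores[:, :2])
    with pytest.raises(ValueError):
        embed_2d(X, method="sammon")


def test_embed_separated_clusters_silhouette():
    from sklearn.metrics import silhouette_score

    X, y, _ = _separable_data(11, n=60)
    for method in ("pca", "tsne"):
        emb = embed_2d(X, method=method, seed=0)
        assert silhouette_score(emb, y) > 0.5
        assert np.allclose(emb, embed_2d(X, method=method, seed=0))
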