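"""Classifier training and evaluation for variant pathogenicity.

Boosted tree ensembles (gradient boosting for the cancer-risk task,
adaptive boosting for the non-cancer-disease task) are evaluated under
three schemes: repeated stratified 10-fold cross-validation
("bootstrapped 10-CV"), jack-knife (leave-one-out), and
leave-one-protein-out (LOPO), where every variant of one gene is held
out together so that a model is never tested on a protein it has seen.
Metrics (balanced accuracy, F1, MCC, recall, precision, AUROC) are
computed from pooled out-of-fold predictions; a greedy forward feature
selection maximises the cross-validated objective.

The ensemble fits are delegated to scikit-learn; the splitting,
pooling, metric formulas, AUROC rank computation, selection, and PCA
are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ValidationScheme",
    "ModelSpec",
    "SelectionTrace",
    "confusion",
    "metrics_from_counts",
    "auroc",
    "make_splits",
    "build_estimator",
    "cross_validate",
    "greedy_forward_select",
    "feature_importance",
    "pca",
    "embed_2d",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    bacc: float
    f1: float
    mcc: float
    recall: float
    precision: float
    auroc: float
    flags: tuple = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "BACC": self.bacc,
            "F1": self.f1,
            "MCC": self.mcc,
            "recall": self.recall,
            "precision": self.precision,
            "AUROC": self.auroc,
        }


@dataclass
class ValidationScheme:
    kind: str = "bootstrapped_kcv"   # bootstrapped_kcv | jackknife | lopo
    k: int = 10
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ModelSpec:
    algorithm: str = "gradient_boosting"   # gradient_boosting | adaptive_boosting
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators <= 0 or self.max_depth <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)   # (feature, objective)
    selected: list = field(default_factory=list)
    importances: dict = field(default_factory=dict)
    flags: tuple = ()


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Confusion counts with an explicit positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    classes = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(classes) > 2:
        raise ValueError(f"non-binary labels: {sorted(classes)}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def auroc(y_true, scores, positive=1) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) formula.

    Midranks handle tied scores; all-tied scores give 0.5.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics_from_counts(
    counts: ConfusionCounts,
    y_true=None,
    scores=None,
    positive=1,
) -> MetricSet:
    """Metric suite from confusion counts (AUROC needs scores).

    Undefined ratios (e.g. precision with no positive calls) are
    reported as 0 and flagged; MCC is 0 when any marginal is empty.
    """
    if counts.n == 0:
        raise ValueError("empty confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags = []
    recall = tp / (tp + fn) if tp + fn else 0.0
    if tp + fn == 0:
        flags.append("recall_undefined")
    precision = tp / (tp + fp) if tp + fp else 0.0
    if tp + fp == 0:
        flags.append("precision_undefined")
    tnr = tn / (tn + fp) if tn + fp else 0.0
    bacc = (recall + tnr) / 2.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    if scores is not None and y_true is not None:
        auc = auroc(y_true, scores, positive=positive)
    else:
        auc = float("nan")
        flags.append("auroc_unavailable")
    return MetricSet(
        bacc=float(bacc), f1=float(f1), mcc=float(mcc),
        recall=float(recall), precision=float(precision), auroc=float(auc),
        flags=tuple(flags),
    )


def make_splits(labels, groups, scheme: ValidationScheme, repetition: int = 0):
    """Train/test index splits for one repetition of a validation scheme.

    ``bootstrapped_kcv`` yields stratified k folds reshuffled from
    ``seed + repetition``; ``jackknife`` yields n singleton test folds;
    ``lopo`` yields one fold per distinct group (gene), holding out all
    of its members. A warning names any fold whose training set lacks a
    class.
    """
    labels = np.asarray(labels)
    n = len(labels)
    idx = np.arange(n)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    if scheme.kind == "bootstrapped_kcv":
        if n < scheme.k:
            raise ValueError("fewer samples than folds")
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(
            n_splits=scheme.k, shuffle=True, random_state=scheme.seed + repetition
        )
        splits = [(tr, te) for tr, te in skf.split(idx.reshape(-1, 1), labels)]
    elif scheme.kind == "jackknife":
        splits = [(np.delete(idx, i), np.array([i])) for i in range(n)]
    elif scheme.kind == "lopo":
        if groups is None:
            raise ValueError("lopo requires groups")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) < 2:
            raise ValueError("lopo requires >= 2 groups")
        splits = [
            (idx[groups != g], idx[groups == g]) for g in uniq
        ]
    else:
        raise ValueError(f"unknown scheme kind {scheme.kind!r}")
    for fold_id, (tr, _) in enumerate(splits):
        if len(np.unique(labels[tr])) < 2:
            warnings.warn(f"fold {fold_id}: a class is absent from training")
    return splits


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn ensemble behind a ModelSpec."""
    if spec.algorithm == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(
            n_estimators=spec.n_estimators,
            max_depth=spec.max_depth,
            learning_rate=spec.learning_rate,
            random_state=spec.seed,
        )
    if spec.algorithm == "adaptive_boosting":
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=spec.max_depth),
            n_estimators=spec.n_estimators,
            learning_rate=spec.learning_rate,
            random_state=spec.seed,
        )
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


def _run_folds(model_spec, X, y, splits):
    """Fit per fold, pool out-of-fold predictions and scores."""
    n = len(y)
    pred = np.empty(n, dtype=int)
    score = np.empty(n, dtype=float)
    for tr, te in splits:
        est = build_estimator(model_spec)
        est.fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
        pos_col = int(np.flatnonzero(est.classes_ == 1)[0]) if 1 in est.classes_ else -1
        proba = est.predict_proba(X[te])
        score[te] = proba[:, pos_col] if pos_col >= 0 else 0.0
    return pred, score


def cross_validate(
    model_spec: ModelSpec,
    X,
    y,
    scheme: ValidationScheme,
    groups=None,
) -> tuple[MetricSet, dict]:
    """Evaluate a model spec under a validation scheme.

    For repeated stratified k-fold CV, out-of-fold predictions are
    pooled within each repetition, a MetricSet computed per repetition,
    and the mean (with sd in the detail dict) reported. Jack-knife and
    LOPO pool across all folds in a single pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    reps = scheme.repetitions if scheme.kind == "bootstrapped_kcv" else 1
    per_rep: list[MetricSet] = []
    detail: dict = {"per_repetition": []}
    for rep in range(reps):
        splits = make_splits(y, groups, scheme, repetition=rep)
        pred, score = _run_folds(model_spec, X, y, splits)
        counts = confusion(y, pred)
        ms = metrics_from_counts(counts, y_true=y, scores=score)
        per_rep.append(ms)
        detail["per_repetition"].append(ms.as_dict())
    mean = {
        k: float(np.mean([m.as_dict()[k] for m in per_rep]))
        for k in per_rep[0].as_dict()
    }
    detail["sd"] = {
        k: float(np.std([m.as_dict()[k] for m in per_rep]))
        for k in per_rep[0].as_dict()
    }
    pooled = MetricSet(
        bacc=mean["BACC"], f1=mean["F1"], mcc=mean["MCC"],
        recall=mean["recall"], precision=mean["precision"], auroc=mean["AUROC"],
    )
    return pooled, detail


def greedy_forward_select(
    features: pd.DataFrame,
    y,
    model_spec: ModelSpec,
    scheme: ValidationScheme,
    groups=None,
    objective: str = "MCC",
    epsilon: float = 0.0,
    max_features: int = 10,
) -> SelectionTrace:
    """Greedy forward feature selection on a cross-validated objective.

    Starting from the empty set, each round adds the candidate feature
    that maximises the cross-validated objective; selection stops when
    the best improvement is <= epsilon or ``max_features`` is reached.
    Ties break by column order, making the trace deterministic for a
    fixed seed.
    """
    candidates = [
        c for c in features.columns
        if np.issubdtype(features[c].dtype, np.number)
        and np.ptp(features[c].to_numpy(dtype=float)) > 0
    ]
    if not candidates:
        return SelectionTrace(flags=("all_constant",))
    y = np.asarray(y, dtype=int)
    selected: list[str] = []
    steps: list[tuple[str, float]] = []
    best_so_far = -np.inf
    while len(selected) < max_features:
        best_feat, best_val = None, -np.inf
        for feat in candidates:
            if feat in selected:
                continue
            X = features[selected + [feat]].to_numpy(dtype=float)
            metrics, _ = cross_validate(model_spec, X, y, scheme, groups=groups)
            val = metrics.as_dict()[objective]
            if val > best_val + 1e-12:
                best_feat, best_val = feat, val
        if best_feat is None:
            break
        improvement = best_val - (best_so_far if np.isfinite(best_so_far) else 0.0)
        if selected and improvement <= epsilon:
            break
        selected.append(best_feat)
        steps.append((best_feat, float(best_val)))
        best_so_far = best_val
    importances: dict[str, float] = {}
    if selected:
        est = build_estimator(model_spec)
        est.fit(features[selected].to_numpy(dtype=float), y)
        importances = feature_importance(est, selected)
    return SelectionTrace(steps=steps, selected=selected, importances=importances)


def feature_importance(fitted_model, feature_names) -> dict[str, float]:
    """Impurity-based importances renormalised to sum to 1."""
    if not hasattr(fitted_model, "feature_importances_"):
        raise ValueError("model is not a fitted ensemble")
    imp = np.asarray(fitted_model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        imp = np.full_like(imp, 1.0 / len(imp))
    else:
        imp = imp / total
    return {name: float(v) for name, v in zip(feature_names, imp)}


def pca(X, n_components: int | None = None):
    """Principal component analysis by covariance eigendecomposition.

    Columns are centred internally. Components are ordered by
    decreasing explained variance, with the deterministic sign
    convention that each component's largest-magnitude loading is
    positive. Returns (scores, loadings, explained variance fractions).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    rank = int(np.sum(eigval > max(eigval.max(), 1.0) * 1e-12)) if eigval.size else 0
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = max(rank, 1)
    eigval_k = eigval[:n_components]
    eigvec_k = eigvec[:, :n_components]
    for j in range(eigvec_k.shape[1]):
        lead = np.argmax(np.abs(eigvec_k[:, j]))
        if eigvec_k[lead, j] < 0:
            eigvec_k[:, j] = -eigvec_k[:, j]
    scores = Xc @ eigvec_k
    total_var = eigval.sum()
    explained = eigval_k / total_var if total_var > 0 else np.zeros_like(eigval_k)
    return scores, eigvec_k, explained


def embed_2d(X, method: str = "pca", seed: int = 0) -> np.ndarray:
    """Seeded 2-D embedding via PCA, t-SNE, or UMAP."""
    X = np.asarray(X, dtype=float)
    if method == "pca":
        scores, _, _ = pca(X, n_components=min(2, X.shape[1]))
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(len(scores))])
        return scores[:, :2]
    if X.shape[0] < 5:
        raise ValueError("neighbour-based embeddings need >= 5 samples")
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
        return TSNE(
            n_components=2, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(X)
    if method == "umap":
        try:
            from umap import UMAP
        except ImportError as exc:
            raise RuntimeError("umap unavailable; use method='pca'") from exc
        return UMAP(n_components=2, random_state=seed).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}; try 'pca'")
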