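"""Out-of-sample prediction of social distance from dyadic similarity vectors.

A linear SVM is trained to predict a dyad's social-distance category from
its vector of per-ROI z-scored similarities.  Because distance categories
are heavily imbalanced, the pipeline uses stratified outer folds,
oversamples minority categories *within each training partition only*
(so chance performance on the held-out data is 1/K), tunes the SVM's C
hyper-parameter by a nested stratified grid search, and assesses
significance by re-running the whole pipeline with training labels
shuffled.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "ClassifierConfig",
    "ClassifierResult",
    "stratified_folds",
    "oversample_training",
    "nested_grid_search",
    "cross_validated_predict",
    "label_permutation_test",
]


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Cross-validation and SVM settings.

    ``c_grid`` defaults to seven logarithmically spaced decade points
    between 1e-3 and 1e3.  ``one_vs_rest`` uses a liblinear SVM (its
    native multiclass handling); ``one_vs_one`` uses the libsvm linear
    kernel (natively one-vs-one).
    """

    n_outer_folds: int = 8
    n_inner_folds: int = 8
    c_grid: tuple[float, ...] = tuple(float(10.0**k) for k in range(-3, 4))
    n_label_perms: int = 1000
    seed: int = 0
    multiclass_scheme: str = "one_vs_rest"
    subject_disjoint_folds: bool = False

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        grid = tuple(float(c) for c in self.c_grid)
        if len(grid) < 1 or any(c <= 0 for c in grid):
            raise ValueError("c_grid entries must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("c_grid must be strictly increasing")
        if self.multiclass_scheme not in ("one_vs_rest", "one_vs_one"):
            raise ValueError("multiclass_scheme must be one_vs_rest or one_vs_one")
        object.__setattr__(self, "c_grid", grid)


@dataclasses.dataclass(frozen=True)
class ClassifierResult:
    categories: tuple[int, ...]
    confusion: np.ndarray            # [K x K], rows = true, row-normalized
    overall_accuracy: float          # pooled over all held-out predictions
    fold_mean_accuracy: float        # unweighted mean of per-fold accuracies
    per_fold_accuracy: np.ndarray
    best_c_per_fold: tuple[float, ...]
    predictions: np.ndarray
    fold_assignment: np.ndarray
    permutation_null: np.ndarray | None = None
    p: float | None = None


def _seed_for(master: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), *map(int, path)]))


def _derived_seed(master: int, *path: int) -> int:
    return int(
        np.random.SeedSequence([int(master), *map(int, path)]).generate_state(1)[0]
        % 2**31
    )


def stratified_folds(categories, k: int, seed: int = 0) -> np.ndarray:
    """Fold id (0..k-1) per observation, preserving category proportions.

    Every category must have at least k members; per-fold category counts
    differ from exact proportionality by at most one item.
    """
    y = np.asarray(categories)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest category has {counts.min()} members; cannot form {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**32)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def oversample_training(features, labels, seed: int = 0):
    """Balance a training set by duplicating minority-class examples.

    Every class is grown to the size of the largest class by repeated
    random passes through its full example set without replacement (so
    every original example is retained, and no example is duplicated a
    second time before all have been duplicated once), with the final
    partial pass a uniform without-replacement subset.
    """
    x = np.asarray(features)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() == 0 or len(classes) == 0:
        raise ValueError("empty class")
    target = counts.max()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        chosen = [idx]  # originals always retained
        deficit = target - idx.size
        while deficit >= idx.size:
            chosen.append(rng.permutation(idx))
            deficit -= idx.size
        if deficit > 0:
            chosen.append(rng.choice(idx, size=deficit, replace=False))
        keep.append(np.concatenate(chosen))
    order = np.concatenate(keep)
    return x[order], y[order]


def _make_estimator(c: float, scheme: str):
    if scheme == "one_vs_rest":
        return LinearSVC(C=c, dual="auto", max_iter=20000, random_state=0)
    return SVC(kernel="linear", C=c)


def nested_grid_search(train_features, train_labels, config: ClassifierConfig,
                       seed: int | None = None) -> float:
    """Pick the C maximizing mean inner-validation accuracy (ties -> smallest).

    The training data are split into inner stratified folds; oversampling
    is applied to each inner training split only, never to validation data.
    """
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    seed = config.seed if seed is None else seed
    folds = stratified_folds(y, config.n_inner_folds, seed=seed)
    scores = np.zeros(len(config.c_grid))
    counts = np.zeros(len(config.c_grid))
    for f in range(config.n_inner_folds):
        tr, va = folds != f, folds == f
        x_tr, y_tr = oversample_training(x[tr], y[tr], seed=_derived_seed(seed, f))
        for ci, c in enumerate(config.c_grid):
            est = _make_estimator(c, config.multiclass_scheme)
            est.fit(x_tr, y_tr)
            scores[ci] += float(np.mean(est.predict(x[va]) == y[va]))
            counts[ci] += 1
    if counts.max() == 0:
        raise RuntimeError("all inner fits failed")
    mean_scores = scores / counts
    return float(config.c_grid[int(np.argmax(mean_scores))])


def _run_cv(x, y, config: ClassifierConfig, folds: np.ndarray,
            train_labels: np.ndarray):
    """Shared CV engine: train on (possibly relabeled) training folds,
    predict every held-out fold.  ``train_labels`` holds the labels used
    for oversampling/tuning/fitting — 1-D for the real analysis or
    [n_folds x n] with one row per fold for label permutations; true ``y``
    is used only for scoring."""
    predictions = np.empty(len(y), dtype=y.dtype)
    best_cs = []
    per_fold_labels = train_labels.ndim == 2
    for f in range(config.n_outer_folds):
        tr, te = folds != f, folds == f
        assert not np.any(tr & te)
        y_tr = (train_labels[f] if per_fold_labels else train_labels)[tr]
        best_c = nested_grid_search(
            x[tr], y_tr, config, seed=_derived_seed(config.seed, 1000 + f)
        )
        x_os, y_os = oversample_training(
            x[tr], y_tr, seed=_derived_seed(config.seed, 2000 + f)
        )
        est = _make_estimator(best_c, config.multiclass_scheme)
        est.fit(x_os, y_os)
        predictions[te] = est.predict(x[te])
        best_cs.append(best_c)
    return predictions, best_cs


def cross_validated_predict(dyad_vectors, categories,
                            config: ClassifierConfig) -> ClassifierResult:
    """Full nested cross-validation of the social-distance classifier.

    For each outer fold the training portion is oversampled, C is tuned by
    the inner search, a linear SVM is retrained on the oversampled
    training portion, and the held-out dyads are predicted.  Returns the
    row-normalized confusion matrix, pooled and fold-averaged accuracies.
    """
    x = np.asarray(dyad_vectors, dtype=float)
    y = np.asarray(categories)
    if not np.isfinite(x).all():
        raise ValueError("non-finite features")
    if len(y) < 4 * config.n_outer_folds:
        raise ValueError("too few dyads for the requested fold count")
    folds = stratified_folds(y, config.n_outer_folds, seed=config.seed)
    predictions, best_cs = _run_cv(x, y, config, folds, train_labels=y)

    cats = np.unique(y)
    k = len(cats)
    confusion = np.zeros((k, k))
    for ti, tc in enumerate(cats):
        sel = y == tc
        for pi, pc in enumerate(cats):
            confusion[ti, pi] = np.mean(predictions[sel] == pc)
    per_fold = np.array(
        [np.mean(predictions[folds == f] == y[folds == f])
         for f in range(config.n_outer_folds)]
    )
    return ClassifierResult(
        categories=tuple(int(c) for c in cats),
        confusion=confusion,
        overall_accuracy=float(np.mean(predictions == y)),
        fold_mean_accuracy=float(per_fold.mean()),
        per_fold_accuracy=per_fold,
        best_c_per_fold=tuple(best_cs),
        predictions=predictions,
        fold_assignment=folds,
    )


def label_permutation_test(dyad_vectors, categories, config: ClassifierConfig,
                           observed: ClassifierResult | None = None) -> ClassifierResult:
    """Label-shuffling significance test of cross-validated accuracy.

    The full pipeline is repeated with the labels of each training fold
    randomly shuffled (held-out labels keep their identity for scoring);
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if config.n_label_perms < 1:
        raise ValueError("n_label_perms must be >= 1")
    x = np.asarray(dyad_vectors, dtype=float)
    y = np.asarray(categories)
    if observed is None:
        observed = cross_validated_predict(x, y, config)
    folds = observed.fold_assignment
    null = np.empty(config.n_label_perms)
    for b in range(config.n_label_perms):
        rng = _seed_for(config.seed, 3000, b)
        # each fold's training labels are shuffled independently
        perm_labels = np.tile(y, (config.n_outer_folds, 1))
        for f in range(config.n_outer_folds):
            tr = np.nonzero(folds != f)[0]
            perm_labels[f, tr] = y[tr][rng.permutation(tr.size)]
        predictions, _ = _run_cv(x, y, config, folds, train_labels=perm_labels)
        null[b] = float(np.mean(predictions == y))
    p = (1.0 + np.sum(null >= observed.overall_accuracy - 1e-12)) / (
        config.n_label_perms + 1.0
    )
    return dataclasses.replace(observed, permutation_null=null, p=float(p))
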