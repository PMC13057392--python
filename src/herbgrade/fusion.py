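"""Mid-level data fusion and grade classification.

Each platform is reduced to PCA scores retaining 95% cumulative
explained variance on autoscaled columns; the per-platform score blocks
are concatenated into a fused feature matrix; and three classifiers are
trained on a seeded, stratified 70/30 split:

* KNN with K = 2 (Euclidean on PCA scores; an even-K vote tie goes to
  the nearest neighbour, implemented via distance weighting);
* a backpropagation network with one hidden layer of 5 sigmoidal
  units, softmax output, cross-entropy loss, at most 1000 iterations;
* a random forest of 500 trees with 3 candidate variables per split.

PCA is fitted on the full matrix before splitting (features first,
then a random split); a leakage-free variant that fits the rotation on
the training rows only is available behind ``fit_on_train``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .containers import DataMatrix
from .synthetic import SyntheticDataset

__all__ = [
    "PcaFeatures",
    "FusedFeatures",
    "SplitSpec",
    "ClassifierConfig",
    "EvalReport",
    "pca_reduce",
    "fuse",
    "split_data",
    "train_and_evaluate",
    "compare_sources",
    "modal_confusion",
]

CLASSIFIER_NAMES = ("knn", "bpnn", "rf")


# ----------------------------------------------------------------------
# PCA feature extraction
# ----------------------------------------------------------------------
@dataclass
class PcaFeatures:
    """Per-platform PCA score block at a cumulative-variance cutoff."""

    scores: pd.DataFrame
    obs: pd.DataFrame
    k: int
    cum_var: float
    platform: str
    components: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    explained_ratio: np.ndarray


def pca_reduce(dm: DataMatrix, cum_var: float = 0.95,
               rows: np.ndarray | None = None) -> PcaFeatures:
    """Smallest-k PCA reaching the cumulative explained-variance cutoff.

    Columns are autoscaled (platforms have incommensurate units);
    component signs are fixed by making the largest-magnitude loading
    positive. ``rows`` restricts the *fit* to a subset (leakage-free
    variant) while scores are always produced for every observation.
    """
    if not 0 < cum_var <= 1:
        raise ValueError("cum_var must be in (0, 1]")
    if dm.n_obs < 2:
        raise ValueError("need at least 2 observations")
    X = dm.X
    fit_rows = np.arange(dm.n_obs) if rows is None else np.asarray(rows)
    mean = X[fit_rows].mean(axis=0)
    sd = X[fit_rows].std(axis=0, ddof=1)
    keep = sd > 0
    sd_safe = np.where(keep, sd, 1.0)
    Z = (X - mean) / sd_safe
    Z = Z[:, keep]
    pca = PCA(svd_solver="full")
    pca.fit(Z[fit_rows])
    ratios = pca.explained_variance_ratio_
    csum = np.cumsum(ratios)
    k = int(np.searchsorted(csum, cum_var - 1e-12) + 1)
    k = min(k, len(ratios))
    comps = pca.components_[:k].copy()
    for a in range(k):
        j = int(np.argmax(np.abs(comps[a])))
        if comps[a, j] < 0:
            comps[a] *= -1
    scores = (Z - pca.mean_) @ comps.T
    cols = [f"{dm.platform or 'PC'}_PC{a + 1}" for a in range(k)]
    return PcaFeatures(
        scores=pd.DataFrame(scores, columns=cols),
        obs=dm.obs.reset_index(drop=True).copy(),
        k=k, cum_var=float(csum[k - 1]), platform=dm.platform,
        components=comps, mean=mean, sd=sd_safe,
        explained_ratio=ratios[:k].copy(),
    )


# ----------------------------------------------------------------------
# fusion
# ----------------------------------------------------------------------
@dataclass
class FusedFeatures:
    """Concatenated PCA score blocks with per-column platform provenance."""

    values: pd.DataFrame
    obs: pd.DataFrame
    blocks: dict[str, list[str]]


def fuse(blocks: list[PcaFeatures]) -> FusedFeatures:
    """Column-wise concatenation of row-aligned PCA blocks."""
    if not blocks:
        raise ValueError("need at least one block")
    ref = blocks[0]
    for other in blocks[1:]:
        _check_rows(ref.obs, other.obs)
    values = pd.concat([b.scores.reset_index(drop=True) for b in blocks], axis=1)
    provenance = {b.platform: list(b.scores.columns) for b in blocks}
    return FusedFeatures(values=values, obs=ref.obs.copy(), blocks=provenance)


def _check_rows(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b):
        raise ValueError(f"row count mismatch: {len(a)} vs {len(b)}")
    keys = [k for k in ("batch_id", "replicate") if k in a.columns and k in b.columns]
    for i in range(len(a)):
        for k in keys:
            if a[k].iloc[i] != b[k].iloc[i]:
                raise ValueError(
                    f"misaligned observation at row {i}: "
                    f"{k}={a[k].iloc[i]!r} vs {b[k].iloc[i]!r}"
                )


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SplitSpec:
    """Seeded stratified train/test partition.

    The global train size is floor(fraction * n), reached by taking
    floor(fraction * n_class) per class and topping up by largest
    fractional remainder. ``study_size`` keeps the pure per-class
    floors (135/60 for the default 195-observation cohort, the sizes
    the study's accuracy percentages back-calculate to).
    """

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0
    study_size: bool = False
    group_by_batch: bool = False


def split_data(obs: pd.DataFrame, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (train_indices, test_indices) over the observation rows."""
    labels = obs["group"].to_numpy()
    n = len(labels)
    if not 0 < spec.train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    if spec.train_fraction == 1.0:
        warnings.warn("train_fraction 1.0 leaves an empty test set")
        return np.arange(n), np.array([], dtype=int)
    rng = np.random.default_rng(spec.seed)

    if spec.group_by_batch:
        batches = obs[["batch_id", "group"]].drop_duplicates()
        tr_b, _ = split_data(batches.rename(columns={"batch_id": "batch_id"}),
                             SplitSpec(spec.train_fraction, spec.stratified,
                                       spec.seed, spec.study_size, False))
        train_batches = set(batches["batch_id"].to_numpy()[tr_b])
        mask = obs["batch_id"].isin(train_batches).to_numpy()
        return np.nonzero(mask)[0], np.nonzero(~mask)[0]

    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2][0]
        raise ValueError(f"class {small!r} has fewer than 2 observations")
    if not spec.stratified:
        perm = rng.permutation(n)
        cut = int(np.floor(spec.train_fraction * n))
        return np.sort(perm[:cut]), np.sort(perm[cut:])

    exact = {c: spec.train_fraction * cnt for c, cnt in zip(classes, counts)}
    take = {c: int(np.floor(v)) for c, v in exact.items()}
    if not spec.study_size:
        target = int(np.floor(spec.train_fraction * n))
        # top up by largest fractional remainder (ties: larger class first)
        order = sorted(classes,
                       key=lambda c: (-(exact[c] - take[c]), -exact[c]))
        i = 0
        while sum(take.values()) < target:
            c = order[i % len(order)]
            if take[c] < int((labels == c).sum()):
                take[c] += 1
            i += 1
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        perm = rng.permutation(len(idx))
        k = take[c]
        train_idx.extend(idx[perm[:k]])
        test_idx.extend(idx[perm[k:]])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


# ----------------------------------------------------------------------
# classifiers
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ClassifierConfig:
    """Fixed study hyperparameters for the three classifiers."""

    knn_k: int = 2
    bpnn_hidden_layers: int = 1
    bpnn_hidden_neurons: int = 5
    bpnn_max_iterations: int = 1000
    rf_n_trees: int = 500
    rf_mtry: int = 3
    seed: int = 0


def _build(name: str, config: ClassifierConfig, n_features: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_k, weights="distance")
    if name == "bpnn":
        hidden = (config.bpnn_hidden_neurons,) * config.bpnn_hidden_layers
        return MLPClassifier(hidden_layer_sizes=hidden, activation="logistic",
                             max_iter=config.bpnn_max_iterations,
                             random_state=config.seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=config.rf_n_trees,
                                      max_features=min(config.rf_mtry, n_features),
                                      random_state=config.seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class EvalReport:
    """Train/test accuracy and the test confusion matrix for one model."""

    source: str
    classifier: str
    train_accuracy: float
    test_accuracy: float
    confusion: pd.DataFrame     # true class (rows) x predicted class (cols)
    n_train: int
    n_test: int


def _confusion(y_true, y_pred, classes) -> pd.DataFrame:
    out = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y_true, y_pred):
        out.loc[t, p] += 1
    return out


def train_and_evaluate(features, labels, config: ClassifierConfig | None = None,
                       split: SplitSpec | tuple | None = None,
                       classifiers=CLASSIFIER_NAMES,
                       source: str = "") -> dict[str, EvalReport]:
    """Train the configured classifiers on a shared split.

    ``split`` is a :class:`SplitSpec` or an explicit (train, test)
    index pair; all randomness flows from the config / spec seeds.
    """
    config = config or ClassifierConfig()
    X = features.to_numpy(dtype=float) if hasattr(features, "to_numpy") else np.asarray(features, float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("features and labels are not row-aligned")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if split is None:
        split = SplitSpec()
    if isinstance(split, SplitSpec):
        obs = pd.DataFrame({"group": labels})
        tr, te = split_data(obs, split)
    else:
        tr, te = split
    reports: dict[str, EvalReport] = {}
    for name in classifiers:
        est = _build(name, config, X.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X[tr], labels[tr])
        train_acc = float(np.mean(est.predict(X[tr]) == labels[tr]))
        pred_te = est.predict(X[te]) if len(te) else np.array([])
        test_acc = float(np.mean(pred_te == labels[te])) if len(te) else float("nan")
        reports[name] = EvalReport(
            source=source, classifier=name,
            train_accuracy=train_acc, test_accuracy=test_acc,
            confusion=_confusion(labels[te], pred_te, classes),
            n_train=len(tr), n_test=len(te),
        )
    return reports


# ----------------------------------------------------------------------
# the consolidated comparison
# ----------------------------------------------------------------------
SOURCES = ("volatile", "nonvolatile", "enose", "etongue", "fused")


def compare_sources(dataset: SyntheticDataset,
                    config: ClassifierConfig | None = None,
                    split_spec: SplitSpec | None = None,
                    cum_var: float = 0.95,
                    classifiers=CLASSIFIER_NAMES):
    """Evaluate every platform and the fused block on one shared split.

    The fused block concatenates exactly the per-platform PCA features
    used by the single-source models. Returns ``(table, reports)``
    where the table has one row per (source, classifier).
    """
    config = config or ClassifierConfig()
    split_spec = split_spec or SplitSpec(seed=config.seed)
    blocks = {name: pca_reduce(dataset.platform(name), cum_var)
              for name in ("volatile", "nonvolatile", "enose", "etongue")}
    fused = fuse(list(blocks.values()))
    labels = fused.obs["group"].to_numpy()
    tr, te = split_data(fused.obs, split_spec)
    reports: dict[tuple[str, str], EvalReport] = {}
    for name in SOURCES:
        feats = fused.values if name == "fused" else blocks[name].scores
        for clf, rep in train_and_evaluate(feats, labels, config, (tr, te),
                                           classifiers, source=name).items():
            reports[(name, clf)] = rep
    rows = [{"source": s, "classifier": c,
             "train_accuracy": r.train_accuracy,
             "test_accuracy": r.test_accuracy}
            for (s, c), r in reports.items()]
    return pd.DataFrame(rows), reports


def modal_confusion(reports) -> tuple[str, str]:
    """Most frequent off-diagonal (true, predicted) pair, order-insensitive.

    Accepts a single report, a dict of reports, or an iterable; returns
    the unordered pair of class labels most often confused on the test
    sets.
    """
    if isinstance(reports, EvalReport):
        reports = [reports]
    elif isinstance(reports, dict):
        reports = list(reports.values())
    total = None
    for rep in reports:
        cm = rep.confusion.astype(float)
        total = cm if total is None else total + cm
    if total is None:
        raise ValueError("no reports given")
    pairs: dict[tuple[str, str], float] = {}
    labs = list(total.index)
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            pairs[(a, b)] = float(total.loc[a, b] + total.loc[b, a])
    return max(pairs, key=pairs.get)
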