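"""PCA feature extraction, fusion, splitting, and grade classifiers."""

import numpy as np
import pandas as pd
import pytest

import herbgrade as hg
from herbgrade.containers import DataMatrix
from herbgrade.design import EffectSpec, StudyDesign
from herbgrade.fusion import (
    ClassifierConfig,
    SplitSpec,
    compare_sources,
    fuse,
    modal_confusion,
    pca_reduce,
    split_data,
    train_and_evaluate,
)


def _matrix(X, groups, platform="test"):
    n = len(groups)
    obs = pd.DataFrame({"batch_id": [f"b{i}" for i in range(n)],
                        "group": groups, "grade": 1, "replicate": 1})
    var = pd.DataFrame(index=pd.Index([f"v{j}" for j in range(X.shape[1])]))
    return DataMatrix(X, obs, var, platform)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
def test_single_direction_gives_one_component(rng):
    t = rng.normal(size=50)
    X = np.outer(t, [1.0, 2.0, -1.0])
    f = pca_reduce(_matrix(X, ["a"] * 25 + ["b"] * 25))
    assert f.k == 1
    assert f.cum_var == pytest.approx(1.0)


def test_k_matches_eigenvalue_cumsum_oracle(rng):
    X = rng.normal(size=(200, 10)) @ np.diag(np.linspace(3, 0.5, 10))
    dm = _matrix(X, ["a"] * 100 + ["b"] * 100)
    f = pca_reduce(dm, cum_var=0.95)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    eig = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
    k_oracle = int(np.searchsorted(np.cumsum(eig) / eig.sum(), 0.95 - 1e-12) + 1)
    assert f.k == k_oracle


def test_full_retention_matches_rank(rng):
    t = rng.normal(size=(30, 2))
    X = t @ rng.normal(size=(2, 6))  # rank-2 data
    f = pca_reduce(_matrix(X, ["a"] * 15 + ["b"] * 15), cum_var=1.0)
    assert f.k == 2


def test_pca_score_properties(default_dataset):
    f = pca_reduce(default_dataset.platform("etongue"))
    scores = f.scores.to_numpy()
    assert np.allclose(scores.mean(axis=0), 0, atol=1e-8)
    variances = scores.var(axis=0)
    assert (np.diff(variances) <= 1e-8).all()
    # deterministic sign: dominant loading positive
    for comp in f.components:
        assert comp[np.argmax(np.abs(comp))] > 0


def test_invalid_cum_var_rejected(default_dataset):
    with pytest.raises(ValueError, match="cum_var"):
        pca_reduce(default_dataset.platform("etongue"), cum_var=1.5)


# ----------------------------------------------------------------------
# fusion
# ----------------------------------------------------------------------
def test_fuse_concatenates_blocks(default_dataset):
    blocks = [pca_reduce(default_dataset.platform(p))
              for p in ("enose", "etongue")]
    fused = fuse(blocks)
    assert fused.values.shape[1] == sum(b.k for b in blocks)
    assert list(fused.blocks) == ["enose", "etongue"]
    single = fuse([blocks[0]])
    pd.testing.assert_frame_equal(single.values, blocks[0].scores)


def test_fuse_rejects_misaligned_rows(default_dataset):
    a = pca_reduce(default_dataset.platform("enose"))
    b = pca_reduce(default_dataset.platform("etongue"))
    b.obs = b.obs.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="row 0"):
        fuse([a, b])


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------
def test_default_and_study_size_splits(default_dataset):
    obs = default_dataset.volatile.obs
    tr, te = split_data(obs, SplitSpec(seed=0))
    assert (len(tr), len(te)) == (136, 59)
    tr2, te2 = split_data(obs, SplitSpec(seed=0, study_size=True))
    assert (len(tr2), len(te2)) == (135, 60)
    # partition: no index on both sides, all indices covered
    assert set(tr) | set(te) == set(range(195))
    assert not set(tr) & set(te)


def test_split_is_seed_deterministic(default_dataset):
    obs = default_dataset.volatile.obs
    a = split_data(obs, SplitSpec(seed=5))
    b = split_data(obs, SplitSpec(seed=5))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_batch_grouped_split_keeps_batches_together(default_dataset):
    obs = default_dataset.volatile.obs
    tr, te = split_data(obs, SplitSpec(seed=1, group_by_batch=True))
    train_batches = set(obs.loc[tr, "batch_id"])
    test_batches = set(obs.loc[te, "batch_id"])
    assert not train_batches & test_batches


def test_full_train_fraction_warns_and_empties_test(default_dataset):
    with pytest.warns(UserWarning, match="empty test"):
        tr, te = split_data(default_dataset.volatile.obs,
                            SplitSpec(train_fraction=1.0))
    assert len(te) == 0


def test_tiny_class_rejected():
    obs = pd.DataFrame({"batch_id": list("abc"), "group": ["x", "x", "y"]})
    with pytest.raises(ValueError, match="'y'"):
        split_data(obs, SplitSpec(seed=0))


# ----------------------------------------------------------------------
# classifiers
# ----------------------------------------------------------------------
def test_separable_blobs_classified_perfectly(rng):
    centers = np.eye(4) * 10
    X = np.vstack([rng.normal(c, 0.3, size=(20, 4)) for c in centers])
    y = np.repeat(["g1", "g2", "g3", "g4"], 20)
    reports = train_and_evaluate(X, y, ClassifierConfig(seed=0), SplitSpec(seed=0))
    for rep in reports.values():
        assert rep.test_accuracy == 1.0
        # confusion trace / test size equals accuracy (exact identity)
        assert np.trace(rep.confusion.to_numpy()) / rep.n_test == rep.test_accuracy


def test_unknown_classifier_rejected(rng):
    X = rng.normal(size=(20, 3))
    y = np.repeat(["a", "b"], 10)
    with pytest.raises(ValueError, match="svm"):
        train_and_evaluate(X, y, classifiers=("svm",))


def test_constant_labels_rejected(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError, match="2 classes"):
        train_and_evaluate(X, np.repeat("a", 10))


def test_compare_sources_structure_and_rf_training(default_dataset):
    table, reports = compare_sources(default_dataset)
    assert set(table["source"]) == {"volatile", "nonvolatile", "enose",
                                    "etongue", "fused"}
    rf = table[table["classifier"] == "rf"]
    assert (rf["train_accuracy"] == 1.0).all()
    assert modal_confusion(reports) == ("AH-HN-1", "AH-HN-2")
    for rep in reports.values():
        assert (rep.n_train, rep.n_test) == (136, 59)
        assert 0 <= rep.test_accuracy <= 1


def test_all_noise_dataset_classifies_at_chance():
    """No planted effects: batch-grouped accuracy sits at the majority rate.

    The leakage-free split is required here — replicate-level splits let
    classifiers recognise batches from their random fingerprints even
    when nothing distinguishes the grades.
    """
    effects = EffectSpec(enose_informative=(), etongue_informative=()).scaled(0.0)
    ds = hg.generate_dataset(StudyDesign(seed=5), effects)
    table, reports = compare_sources(
        ds, split_spec=SplitSpec(seed=5, group_by_batch=True),
        classifiers=("rf",))
    rep = next(iter(reports.values()))
    majority = ds.volatile.obs["group"].value_counts(normalize=True).max()
    bound = majority + 3 * np.sqrt(majority * (1 - majority) / rep.n_test)
    assert (table["test_accuracy"] <= bound).all()
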