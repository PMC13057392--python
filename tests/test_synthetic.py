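"""Synthetic cohort generator: structure, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

import herbgrade as hg
from herbgrade.design import (
    EffectSpec,
    NoiseModel,
    StudyDesign,
    default_effects,
    default_noise,
    default_panel,
)
from herbgrade.synthetic import (
    generate_dataset,
    generate_evaluator_counts,
    repeated_acquisition_rsd,
    simulate_enose_acquisition,
    simulate_etongue_acquisition,
)


def test_default_structure(default_dataset):
    ds = default_dataset
    for dm in ds.tables().values():
        assert dm.n_obs == 195
        assert dm.obs["batch_id"].nunique() == 39
        assert (dm.X > 0).all()
    assert ds.volatile.n_var == 49
    assert int(ds.volatile.var["shared_peak"].sum()) == 22
    assert ds.nonvolatile.n_var == 51
    assert ds.nonvolatile.var["ion_mode"].value_counts().to_dict() == {
        "positive": 30, "negative": 21}
    assert ds.enose.n_var == 18
    assert ds.etongue.n_var == 7
    # group sizes from the study design
    batches = ds.volatile.obs.drop_duplicates("batch_id")
    assert batches["group"].value_counts().to_dict() == {
        "AH-HN-1": 13, "ZJ": 10, "HB": 9, "AH-HN-2": 7}


def test_tables_share_row_alignment(default_dataset):
    ds = default_dataset
    ref = ds.volatile.obs
    for dm in ds.tables().values():
        pd.testing.assert_frame_equal(dm.obs, ref)
        dm.check_aligned(ds.volatile)


def test_identical_seed_gives_byte_identical_tables():
    a = generate_dataset(StudyDesign(seed=7))
    b = generate_dataset(StudyDesign(seed=7))
    for name in ("volatile", "nonvolatile", "enose", "etongue"):
        assert np.array_equal(a.platform(name).X, b.platform(name).X)
    pd.testing.assert_frame_equal(a.evaluator_counts, b.evaluator_counts)


def test_zero_effect_scale_equalises_planted_group_means():
    effects = default_effects().scaled(0.0)
    means = effects.group_log_means("volatile", default_panel(), 0.02,
                                    ["ZJ", "AH-HN-1", "AH-HN-2", "HB"])
    for g in ("AH-HN-1", "AH-HN-2", "HB"):
        assert np.allclose(means[g], means["ZJ"])


def test_shared_volatile_group_ordering(default_dataset):
    bm = default_dataset.volatile.batch_means().to_table()
    for comp in ("atractylone", "aromadendrene", "γ-elemene", "caryophyllene"):
        m = bm.groupby("group")[comp].mean()
        assert m["AH-HN-1"] > m["AH-HN-2"] > m["ZJ"] > m["HB"]


def test_ordering_recovery_across_seeds():
    violations = 0
    for seed in range(500, 530):
        bm = generate_dataset(StudyDesign(seed=seed)).volatile.batch_means().to_table()
        for comp in ("atractylone", "aromadendrene", "γ-elemene", "caryophyllene"):
            m = bm.groupby("group")[comp].mean()
            violations += not (m["AH-HN-1"] > m["AH-HN-2"] > m["ZJ"] > m["HB"])
    assert violations <= 1  # >= 0.99 recovery probability per constraint


def test_nonvolatile_planted_contrasts(default_dataset):
    bm = (default_dataset.nonvolatile.batch_means().to_table()
          .groupby("group").mean(numeric_only=True))
    assert bm.loc["ZJ", "isoatractylode A"] > bm.loc["HB", "isoatractylode A"]
    assert bm.loc["ZJ", "atractylenolide I"] > bm.loc["HB", "atractylenolide I"]
    assert bm.loc["HB", "sucrose"] > bm.loc["ZJ", "sucrose"]


# ----------------------------------------------------------------------
# acquisition protocols
# ----------------------------------------------------------------------
def test_enose_discards_first_injection(default_dataset):
    lat = default_dataset.enose_latents.iloc[0].to_numpy()
    retained = simulate_enose_acquisition(lat, default_dataset.truth.enose_loadings,
                                          default_noise(), n_injections=4, rng=0)
    assert retained.shape == (3, 18)
    with pytest.raises(ValueError, match="at least 2"):
        simulate_enose_acquisition(lat, default_dataset.truth.enose_loadings,
                                   default_noise(), n_injections=1)


def test_noiseless_acquisitions_are_identical(default_dataset):
    lat = default_dataset.enose_latents.iloc[0].to_numpy()
    silent = NoiseModel(drift_sigma=0.0, sensor_sigma=0.0)
    retained = simulate_enose_acquisition(lat, default_dataset.truth.enose_loadings,
                                          silent, n_injections=5, rng=1)
    assert np.allclose(retained, retained[0])
    avg = simulate_etongue_acquisition(
        default_dataset.etongue_latents.iloc[0].to_numpy(),
        default_dataset.truth.etongue_loadings, silent, rng=1)
    noiseless = (default_dataset.truth.etongue_loadings.to_numpy()
                 @ default_dataset.etongue_latents.iloc[0].to_numpy())
    assert np.allclose(avg, noiseless)


def test_etongue_averages_last_five_of_nine(default_dataset):
    lat = default_dataset.etongue_latents.iloc[0].to_numpy()
    loadings = default_dataset.truth.etongue_loadings
    a = simulate_etongue_acquisition(lat, loadings, default_noise(),
                                     n_measurements=9, n_discard=4, rng=5)
    b = simulate_etongue_acquisition(lat, loadings, default_noise(),
                                     n_measurements=9, n_discard=4, rng=5)
    assert np.array_equal(a, b)  # seeded determinism
    assert a.shape == (7,)
    with pytest.raises(ValueError, match="smaller"):
        simulate_etongue_acquisition(lat, loadings, default_noise(),
                                     n_measurements=4, n_discard=4)


def test_repeat_acquisition_rsd_below_three_percent(default_dataset):
    rsd = repeated_acquisition_rsd(default_dataset.enose_latents.iloc[0].to_numpy(),
                                   default_dataset.truth.enose_loadings,
                                   default_dataset.noise, n_repeats=6, rng=42)
    assert rsd.max() < 3.0


# ----------------------------------------------------------------------
# evaluator counts
# ----------------------------------------------------------------------
def test_evaluator_counts_sum_to_panel():
    counts = generate_evaluator_counts(StudyDesign(seed=1), panel_size=10, rng=1)
    sums = counts.groupby(["batch_id", "criterion"])["count"].sum()
    assert (sums == 10).all()
    assert counts["batch_id"].nunique() == 39


def test_degenerate_target_puts_all_counts_on_one_level():
    counts = generate_evaluator_counts(
        StudyDesign(seed=1), panel_size=10,
        score_targets={g: 70.0 for g in ("ZJ", "AH-HN-1", "AH-HN-2", "HB")},
        rng=0)
    level2 = counts[counts["level"] == 2]
    assert (level2["count"] == 10).all()


def test_score_target_outside_scale_rejected():
    with pytest.raises(ValueError, match="outside attainable"):
        generate_evaluator_counts(
            StudyDesign(seed=1),
            score_targets={g: 95.0 for g in ("ZJ", "AH-HN-1", "AH-HN-2", "HB")},
            rng=0)


# ----------------------------------------------------------------------
# input validation
# ----------------------------------------------------------------------
def test_unknown_compound_in_effect_spec_is_named():
    bad = EffectSpec(volatile_shifts={"not-a-compound": {"HB": 2.0}})
    with pytest.raises(ValueError, match="not-a-compound"):
        generate_dataset(StudyDesign(seed=1), bad)


def test_unknown_sensor_in_informative_set_is_named():
    bad = EffectSpec(etongue_informative=("PKS", "XXX"))
    with pytest.raises(ValueError, match="XXX"):
        generate_dataset(StudyDesign(seed=1), bad)


def test_non_positive_sigma_rejected():
    with pytest.raises(ValueError, match="batch_sigma"):
        generate_dataset(StudyDesign(seed=1), noise=NoiseModel(batch_sigma=0.0))


def test_truth_record_matches_planted_sets(default_dataset):
    truth = default_dataset.truth
    assert len(truth.union_set("volatile")) == 25
    assert truth.shared_set("volatile") == {
        "atractylone", "aromadendrene", "γ-elemene", "caryophyllene"}
    assert len(truth.union_set("nonvolatile")) == 25
    assert truth.shared_set("nonvolatile") == {
        "isoatractylode A", "β-sitosterol", "atractylenolide I",
        "maltose", "sucrose",
        "6,9-dihydroxy-3,3a-dihydro atractylenolide III"}
    modes = default_dataset.nonvolatile.var["ion_mode"]
    counts = modes.loc[sorted(truth.union_set("nonvolatile"))].value_counts()
    assert counts.to_dict() == {"positive": 17, "negative": 8}
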