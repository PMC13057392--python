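"""Seeded synthetic cohort generator for the four measurement platforms.

The generator emulates the statistical structure the downstream
analysis assumes, so every stage is testable without instrument data:

* compound abundances are log-normal with a per-variable baseline, a
  planted group effect (in pooled-SD units), a per-variable batch-level
  biological effect, and replicate-level technical noise; the tables
  represent internal-standard-normalised relative contents, so no
  shared concentration factor survives normalisation;
* sensor responses are non-negative linear combinations of latent
  channel abundances through a fixed loading matrix, times
  multiplicative technical noise. Informative sensors load on
  grade-varying channels (derived from the planted compound profiles),
  uninformative sensors only on the grade-constant baseline channel,
  which drifts batch to batch;
* acquisition protocols are modelled feature-level: the gas array
  discards the first injection and keeps the rest, the taste array
  averages the last ``n - discard`` of ``n`` measurements;
* evaluator counts are multinomial draws whose expectation places the
  fuzzy sensory score at a per-batch target; targets couple positively
  to four named compounds so score-compound correlations are
  recoverable.

All randomness flows from named substreams of the design seed, so equal
inputs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DataMatrix
from .design import (
    CompoundPanel,
    EffectSpec,
    NoiseModel,
    StudyDesign,
    default_effects,
    default_noise,
    default_panel,
)

__all__ = [
    "SyntheticDataset",
    "generate_dataset",
    "simulate_enose_acquisition",
    "simulate_etongue_acquisition",
    "generate_evaluator_counts",
    "repeated_acquisition_rsd",
    "CRITERIA",
    "LEVEL_VALUES",
]

#: default sensory criteria and level values (best to worst)
CRITERIA = ("sectional color", "chrysanthemum pattern", "oil spots",
            "number per kilogram")
LEVEL_VALUES = (90.0, 70.0, 50.0, 30.0)

_STREAMS = ("volatile", "nonvolatile", "enose", "etongue", "sensory")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


# ----------------------------------------------------------------------
# acquisition simulators
# ----------------------------------------------------------------------
def _noiseless_response(latents, loadings) -> np.ndarray:
    L = loadings.to_numpy() if hasattr(loadings, "to_numpy") else np.asarray(loadings)
    u = np.asarray(latents, dtype=float)
    if (u < 0).any():
        raise ValueError("latent abundances must be non-negative")
    return L @ u


def _noisy_draws(base: np.ndarray, noise: NoiseModel, n: int, rng) -> np.ndarray:
    """n acquisitions: shared per-acquisition gain x per-sensor noise."""
    gain = np.exp(noise.drift_sigma * rng.standard_normal((n, 1)))
    eps = np.exp(noise.sensor_sigma * rng.standard_normal((n, base.size)))
    return base * gain * eps


def simulate_enose_acquisition(latents, loadings, noise: NoiseModel,
                               n_injections: int, rng=None) -> np.ndarray:
    """Simulate consecutive gas-array injections of one sample.

    The first injection is discarded; the retained responses are the
    loading matrix applied to the latent abundances under multiplicative
    acquisition noise (a shared run gain plus per-sensor noise).
    Returns an ``(n_injections - 1) x n_sensors`` array.
    """
    if n_injections < 2:
        raise ValueError("n_injections must be at least 2 (first is discarded)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base = _noiseless_response(latents, loadings)
    return _noisy_draws(base, noise, n_injections, rng)[1:]


def simulate_etongue_acquisition(latents, loadings, noise: NoiseModel,
                                 n_measurements: int = 9, n_discard: int = 4,
                                 rng=None) -> np.ndarray:
    """Average the last ``n_measurements - n_discard`` simulated readings."""
    if n_discard >= n_measurements:
        raise ValueError("n_discard must be smaller than n_measurements")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base = _noiseless_response(latents, loadings)
    return _noisy_draws(base, noise, n_measurements, rng)[n_discard:].mean(axis=0)


def repeated_acquisition_rsd(latents, loadings, noise: NoiseModel,
                             n_repeats: int = 6, rng=None) -> pd.Series:
    """Per-sensor relative standard deviation (%) of repeated acquisitions."""
    retained = simulate_enose_acquisition(latents, loadings, noise,
                                          n_injections=n_repeats + 1, rng=rng)
    rsd = retained.std(axis=0, ddof=1) / retained.mean(axis=0) * 100.0
    index = loadings.index if hasattr(loadings, "index") else None
    return pd.Series(rsd, index=index, name="RSD_percent")


# ----------------------------------------------------------------------
# evaluator counts
# ----------------------------------------------------------------------
def _target_probabilities(target: float, level_values) -> np.ndarray:
    """Two-point distribution over adjacent levels with the exact mean."""
    v = np.asarray(level_values, dtype=float)
    if not np.all(np.diff(v) < 0):
        raise ValueError("level values must be strictly decreasing")
    if target > v[0] or target < v[-1]:
        raise ValueError(
            f"score target {target} outside attainable range [{v[-1]}, {v[0]}]"
        )
    p = np.zeros(v.size)
    for j in range(v.size - 1):
        if v[j] >= target >= v[j + 1]:
            span = v[j] - v[j + 1]
            p[j] = (target - v[j + 1]) / span
            p[j + 1] = 1.0 - p[j]
            return p
    p[0] = 1.0  # target == best level
    return p


def _counts_for_target(target: float, panel_size: int, level_values,
                       concentration: float, rng) -> np.ndarray:
    p = _target_probabilities(target, level_values)
    if np.isfinite(concentration):
        p = rng.dirichlet(concentration * p + 1e-9)
    return rng.multinomial(panel_size, p)


def generate_evaluator_counts(
    design: StudyDesign,
    panel_size: int = 10,
    score_targets=None,
    level_values=LEVEL_VALUES,
    criteria=CRITERIA,
    concentration: float = np.inf,
    rng=None,
) -> pd.DataFrame:
    """Long-format evaluator counts (batch_id, criterion, level, count).

    For each batch and criterion, counts over the quality levels are a
    multinomial draw of ``panel_size`` evaluators whose expectation puts
    the fuzzy score at the group's target. ``concentration`` controls
    Dirichlet overdispersion of the level probabilities (``inf`` keeps
    the exact two-point expectation).
    """
    if panel_size < 1:
        raise ValueError("panel_size must be at least 1")
    from .design import DEFAULT_SENSORY_TARGETS

    score_targets = dict(score_targets or DEFAULT_SENSORY_TARGETS)
    batches = design.batch_table()
    targets = batches["group"].map(score_targets)
    if targets.isna().any():
        missing = batches.loc[targets.isna(), "group"].iloc[0]
        raise ValueError(f"no score target for group {missing!r}")
    targets.index = batches["batch_id"]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _counts_table(targets, panel_size, level_values, criteria,
                         concentration, rng)


def _counts_table(batch_targets: pd.Series, panel_size, level_values, criteria,
                  concentration, rng) -> pd.DataFrame:
    rows = []
    for batch_id, target in batch_targets.items():
        for crit in criteria:
            counts = _counts_for_target(float(target), panel_size, level_values,
                                        concentration, rng)
            for level, c in enumerate(counts, start=1):
                rows.append({"batch_id": batch_id, "criterion": crit,
                             "level": level, "count": int(c)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# dataset
# ----------------------------------------------------------------------
@dataclass
class SyntheticDataset:
    """Four aligned platform tables plus sensory inputs and ground truth."""

    design: StudyDesign
    noise: NoiseModel
    truth: EffectSpec
    volatile: DataMatrix
    nonvolatile: DataMatrix
    enose: DataMatrix
    etongue: DataMatrix
    evaluator_counts: pd.DataFrame
    sensory_targets: pd.Series
    enose_latents: pd.DataFrame
    etongue_latents: pd.DataFrame

    def tables(self) -> dict[str, DataMatrix]:
        return {"volatile": self.volatile, "nonvolatile": self.nonvolatile,
                "enose": self.enose, "etongue": self.etongue}

    def platform(self, name: str) -> DataMatrix:
        return self.tables()[name]


def _compound_block(platform: str, design: StudyDesign, effects: EffectSpec,
                    noise: NoiseModel, panel: CompoundPanel, rng,
                    obs: pd.DataFrame):
    groups = [g.name for g in design.groups]
    means = effects.group_log_means(platform, panel, noise.pooled_sd(), groups)
    batches = design.batch_table()
    nb, p = len(batches), means.shape[0]
    idio = rng.normal(0.0, noise.batch_sigma, (nb, p))
    log_batch = means.loc[:, batches["group"]].to_numpy().T + idio
    # batch-level analytical confound along the platform's grade axis
    # (sample-preparation variation; independent between platforms, so
    # it limits each single platform but averages out under fusion)
    axis = effects.grade_axis(platform)
    u = np.array([axis.get(v, 0.0) for v in means.index])
    conf = rng.normal(0.0, noise.confound_sigma(platform), nb)
    log_assay = log_batch + np.outer(conf, u)
    m = design.replicates_per_batch
    entries = getattr(panel, platform)
    # per-acquisition response drift shared within each chemical class
    classes = [c.chem_class for c in entries]
    class_levels = list(dict.fromkeys(classes))
    class_draw = rng.normal(0.0, noise.class_sigma, (nb * m, len(class_levels)))
    class_factor = class_draw[:, [class_levels.index(c) for c in classes]]
    eps = rng.normal(0.0, noise.replicate_sigma, (nb * m, p))
    X = np.exp(np.repeat(log_assay, m, axis=0) + class_factor + eps)
    var = pd.DataFrame(index=pd.Index([c.id for c in entries], name="variable"))
    var["platform"] = platform
    var["chem_class"] = [c.chem_class for c in entries]
    if platform == "volatile":
        var["shared_peak"] = [c.shared_peak for c in entries]
    else:
        var["ion_mode"] = [c.ion_mode for c in entries]
    dm = DataMatrix(X, obs.copy(), var, platform)
    log_batch_df = pd.DataFrame(log_batch, index=batches["batch_id"],
                                columns=means.index)
    return dm, log_batch_df


def _sensor_block(platform: str, loadings: pd.DataFrame,
                  latents: pd.DataFrame, design: StudyDesign,
                  noise: NoiseModel, rng, obs: pd.DataFrame) -> DataMatrix:
    m = design.replicates_per_batch
    rows = []
    for _, lat in latents.iterrows():
        for _ in range(m):
            if platform == "enose":
                # one valid injection per observation (first discarded)
                rows.append(simulate_enose_acquisition(
                    lat.to_numpy(), loadings, noise, n_injections=2, rng=rng)[0])
            else:
                rows.append(simulate_etongue_acquisition(
                    lat.to_numpy(), loadings, noise, rng=rng))
    var = pd.DataFrame(index=pd.Index(loadings.index, name="variable"))
    var["platform"] = platform
    return DataMatrix(np.vstack(rows), obs.copy(), var, platform)


def generate_dataset(
    design: StudyDesign | None = None,
    effects: EffectSpec | None = None,
    noise: NoiseModel | None = None,
    panel: CompoundPanel | None = None,
) -> SyntheticDataset:
    """Generate the full aligned synthetic cohort.

    Identical ``(design, effects, noise)`` produce byte-identical
    tables. Raises for unknown compound ids in the effect spec, unknown
    sensors in the informative sets, or non-positive noise sigmas.
    """
    design = design or StudyDesign()
    effects = effects or default_effects()
    noise = noise or default_noise()
    panel = panel or default_panel()
    noise.validate()
    for sensors, loadings, label in (
        (effects.enose_informative, effects.enose_loadings, "E-nose"),
        (effects.etongue_informative, effects.etongue_loadings, "E-tongue"),
    ):
        unknown = [s for s in sensors if s not in loadings.index]
        if unknown:
            raise ValueError(f"unknown {label} sensor in informative set: {unknown[0]!r}")

    rngs = _streams(design.seed)
    obs = design.observation_table()
    batches = design.batch_table()

    volatile, vol_logs = _compound_block("volatile", design, effects, noise,
                                         panel, rngs["volatile"], obs)
    nonvolatile, nonvol_logs = _compound_block("nonvolatile", design, effects,
                                               noise, panel,
                                               rngs["nonvolatile"], obs)

    # --- latent channels driving the sensor arrays --------------------
    base_vol = panel.base_log_abundance("volatile")
    base_nonvol = panel.base_log_abundance("nonvolatile")
    named_vol = [v for v in
                 ("caryophyllene", "γ-elemene", "aromadendrene", "atractylone")
                 if v in vol_logs.columns]
    dev_vol = vol_logs[named_vol] - base_vol[named_vol]
    rng_en = rngs["enose"]
    enose_latents = pd.DataFrame({
        "baseline": np.ones(len(batches)),
        # headspace-equilibration variation blurs the aroma channel at
        # batch level, independently of the chromatographic confound
        "aroma": np.exp(2.2 * dev_vol.mean(axis=1).to_numpy()
                        + rng_en.normal(0.0, 0.10, len(batches))),
        "zj_marker": np.exp(
            0.45 * effects.effect_scale
            * (batches["group"] == "ZJ").to_numpy(dtype=float)
            + rng_en.normal(0.0, 0.02, len(batches))
        ),
        "hb_marker": np.exp(
            0.45 * effects.effect_scale
            * (batches["group"] == "HB").to_numpy(dtype=float)
            + rng_en.normal(0.0, 0.02, len(batches))
        ),
        # growth-age note: the older (2-year) middle grade smells subtly
        # different, a weak channel only fusion can exploit reliably
        "age_marker": np.exp(
            0.07 * effects.effect_scale
            * (batches["group"] == "AH-HN-1").to_numpy(dtype=float)
            + rng_en.normal(0.0, 0.055, len(batches))
        ),
    }, index=batches["batch_id"])
    enose = _sensor_block("enose", effects.enose_loadings,
                          enose_latents[list(effects.enose_loadings.columns)],
                          design, noise, rng_en, obs)

    rng_et = rngs["etongue"]
    taste_anchor = "atractylenolide I"
    dev_taste = (nonvol_logs[taste_anchor] - base_nonvol[taste_anchor]
                 if taste_anchor in nonvol_logs.columns
                 else pd.Series(0.0, index=nonvol_logs.index))
    etongue_latents = pd.DataFrame({
        "baseline": np.ones(len(batches)),
        "taste": np.exp(2.0 * dev_taste.to_numpy()
                        + rng_et.normal(0.0, 0.022, len(batches))),
    }, index=batches["batch_id"])
    etongue = _sensor_block("etongue", effects.etongue_loadings,
                            etongue_latents[list(effects.etongue_loadings.columns)],
                            design, noise, rng_et, obs)

    # --- sensory targets coupled to the planted compounds -------------
    rng_sens = rngs["sensory"]
    base_targets = batches["group"].map(dict(effects.sensory_targets))
    base_targets.index = batches["batch_id"]
    zsum = pd.Series(0.0, index=batches["batch_id"])
    for comp, coef in effects.sensory_coupling.items():
        logs = vol_logs if comp in vol_logs.columns else nonvol_logs
        if comp not in logs.columns:
            raise ValueError(f"unknown compound id in sensory coupling: {comp!r}")
        col = logs[comp]
        z = (col - col.mean()) / max(col.std(ddof=0), 1e-12)
        zsum += coef * z
    zsum /= max(sum(abs(c) for c in effects.sensory_coupling.values()), 1e-12)
    targets = (base_targets + effects.sensory_coupling_scale * zsum).clip(42.0, 82.0)
    counts = _counts_table(targets, panel_size=10, level_values=LEVEL_VALUES,
                           criteria=CRITERIA, concentration=np.inf, rng=rng_sens)

    return SyntheticDataset(
        design=design, noise=noise, truth=effects,
        volatile=volatile, nonvolatile=nonvolatile,
        enose=enose, etongue=etongue,
        evaluator_counts=counts, sensory_targets=targets,
        enose_latents=enose_latents, etongue_latents=etongue_latents,
    )
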