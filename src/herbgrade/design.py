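"""Study design, compound panels, planted effects, and noise model.

Defaults describe a four-grade herbal grading cohort:

* 39 batches in four specification groups — ZJ (grade 1, n=10),
  AH-HN-1 (grade 2, n=13), AH-HN-2 (grade 3, n=7), HB (grade 4, n=9) —
  with five replicate observations per batch (195 rows per platform);
* a 49-compound volatile panel (22 flagged as shared peaks) and a
  51-compound non-volatile panel annotated with ESI ion mode
  (30 positive / 21 negative);
* an 18-sensor metal-oxide gas-sensor array (E-nose) and a 7-sensor
  taste-sensor array (E-tongue);
* planted grade effects expressed in pooled-SD units on the log scale,
  chosen so the two middle grades (AH-HN-1 / AH-HN-2) are the closest
  pair on every platform.

Only ten compounds carry real names (they anchor the planted shared
differentials); the rest are synthetic placeholders ``V..``/``N..``
with chemical-class tags, since names play no computational role.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

# ----------------------------------------------------------------------
# study design
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GroupSpec:
    name: str
    grade: int
    n_batches: int


DEFAULT_GROUPS = (
    GroupSpec("ZJ", 1, 10),
    GroupSpec("AH-HN-1", 2, 13),
    GroupSpec("AH-HN-2", 3, 7),
    GroupSpec("HB", 4, 9),
)


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: groups, replicate count, master seed."""

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    replicates_per_batch: int = 5
    seed: int = 42

    def __post_init__(self):
        if self.replicates_per_batch < 1:
            raise ValueError("replicates_per_batch must be positive")
        for g in self.groups:
            if g.n_batches < 1:
                raise ValueError(f"group {g.name!r} must have at least one batch")

    @property
    def n_batches(self) -> int:
        return sum(g.n_batches for g in self.groups)

    @property
    def n_observations(self) -> int:
        return self.n_batches * self.replicates_per_batch

    def batch_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for i in range(1, g.n_batches + 1):
                rows.append({"batch_id": f"{g.name}-{i:02d}",
                             "group": g.name, "grade": g.grade})
        return pd.DataFrame(rows)

    def observation_table(self) -> pd.DataFrame:
        b = self.batch_table()
        reps = []
        for _, row in b.iterrows():
            for r in range(1, self.replicates_per_batch + 1):
                reps.append({**row.to_dict(), "replicate": r})
        return pd.DataFrame(reps)


# ----------------------------------------------------------------------
# compound panels
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Compound:
    id: str
    chem_class: str
    shared_peak: bool = False
    ion_mode: str | None = None  # "positive" | "negative" for LC features


NAMED_VOLATILES = ("caryophyllene", "γ-elemene", "aromadendrene", "atractylone")

NAMED_NONVOLATILES = (
    "isoatractylode A",
    "β-sitosterol",
    "atractylenolide I",
    "maltose",
    "sucrose",
    "6,9-dihydroxy-3,3a-dihydro atractylenolide III",
)

_VOL_CLASSES = ("terpene", "alkene", "ketone", "ester", "alcohol")
_NONVOL_CLASSES = ("lactone", "phenolic acid", "sugar", "amino acid", "sterol")


def _volatile_entries() -> tuple[Compound, ...]:
    entries = [
        Compound("caryophyllene", "terpene", shared_peak=True),
        Compound("γ-elemene", "terpene", shared_peak=True),
        Compound("aromadendrene", "terpene", shared_peak=True),
        Compound("atractylone", "ketone", shared_peak=True),
    ]
    for i in range(5, 50):
        entries.append(
            Compound(f"V{i:02d}", _VOL_CLASSES[i % len(_VOL_CLASSES)],
                     shared_peak=(i <= 22))
        )
    return tuple(entries)


def _nonvolatile_entries() -> tuple[Compound, ...]:
    entries = [
        Compound("isoatractylode A", "lactone", ion_mode="positive"),
        Compound("β-sitosterol", "sterol", ion_mode="positive"),
        Compound("atractylenolide I", "lactone", ion_mode="positive"),
        Compound("maltose", "sugar", ion_mode="negative"),
        Compound("sucrose", "sugar", ion_mode="negative"),
        Compound("6,9-dihydroxy-3,3a-dihydro atractylenolide III", "lactone",
                 ion_mode="positive"),
    ]
    for i in range(7, 52):
        mode = "positive" if i <= 32 else "negative"
        entries.append(
            Compound(f"N{i:02d}", _NONVOL_CLASSES[i % len(_NONVOL_CLASSES)],
                     ion_mode=mode)
        )
    return tuple(entries)


@dataclass(frozen=True)
class CompoundPanel:
    """Variable panels for the two chromatographic platforms."""

    volatile: tuple[Compound, ...] = field(default_factory=_volatile_entries)
    nonvolatile: tuple[Compound, ...] = field(default_factory=_nonvolatile_entries)

    def ids(self, platform: str) -> list[str]:
        return [c.id for c in getattr(self, platform)]

    def ion_modes(self) -> pd.Series:
        return pd.Series({c.id: c.ion_mode for c in self.nonvolatile})

    def base_log_abundance(self, platform: str) -> pd.Series:
        """Deterministic per-compound baseline log abundance.

        Drawn once from a fixed stream so baselines never depend on the
        dataset seed; spread over roughly two orders of magnitude.
        """
        ids = self.ids(platform)
        rng = np.random.default_rng(
            20240915 if platform == "volatile" else 20240916
        )
        return pd.Series(rng.normal(0.0, 1.0, len(ids)), index=ids)


def default_panel() -> CompoundPanel:
    return CompoundPanel()


# ----------------------------------------------------------------------
# sensors
# ----------------------------------------------------------------------
ENOSE_SENSORS = tuple(f"S{i}" for i in range(1, 19))
ETONGUE_SENSORS = ("AHS", "PKS", "CTS", "NMS", "CPS", "ANS", "SCS")

ENOSE_INFORMATIVE = ("S17", "S11", "S1", "S18", "S13", "S12", "S14", "S5", "S7")
ETONGUE_INFORMATIVE = ("PKS", "ANS")

# latent channels: [baseline matrix, aroma index, ZJ marker, HB marker]
# for the gas array; [baseline matrix, taste index] for the taste array.
# Informative sensors load on grade-varying channels; the rest only on
# the (batch-drifting) baseline. The ZJ and HB markers reflect the two
# end grades' distinct processing (smoke-drying vs seedling cultivation)
# and give the multiclass model genuine signal in every predictive
# direction.
_ENOSE_SIGNAL = {
    "S17": (1.6, 0.8, 0.0, 0.0), "S11": (1.5, 0.6, 0.0, 0.4),
    "S1": (1.4, 0.7, 0.0, 0.0), "S18": (1.3, 0.6, 0.0, 0.0),
    "S13": (1.25, 0.0, 0.5, 0.0), "S12": (1.2, 0.0, 0.5, 0.0),
    "S14": (1.15, 0.0, 0.45, 0.0), "S5": (1.1, 0.0, 0.45, 0.4),
    "S7": (1.05, 0.0, 0.4, 0.35),
}
_ENOSE_BASE = {
    "S2": 1.2, "S3": 2.1, "S4": 1.6, "S6": 2.4, "S8": 1.9,
    "S9": 1.1, "S10": 2.2, "S15": 1.4, "S16": 2.0,
}


def default_enose_loadings() -> pd.DataFrame:
    rows = {}
    for s in ENOSE_SENSORS:
        if s in _ENOSE_SIGNAL:
            aroma, zj, hb, age = _ENOSE_SIGNAL[s]
            rows[s] = (0.5, aroma, zj, hb, age)
        else:
            rows[s] = (_ENOSE_BASE[s], 0.0, 0.0, 0.0, 0.0)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["baseline", "aroma", "zj_marker", "hb_marker", "age_marker"],
    ).loc[list(ENOSE_SENSORS)]


def default_etongue_loadings() -> pd.DataFrame:
    rows = {
        "AHS": (1.8, 0.0), "PKS": (0.5, 1.8), "CTS": (1.2, 0.0),
        "NMS": (2.1, 0.0), "CPS": (1.5, 0.0), "ANS": (0.6, 1.4),
        "SCS": (1.0, 0.0),
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["baseline", "taste"]
    ).loc[list(ETONGUE_SENSORS)]


# ----------------------------------------------------------------------
# planted effects
# ----------------------------------------------------------------------
def _alt(i: int, magnitude: float = 5.0) -> float:
    return magnitude if i % 2 == 0 else -magnitude


def _default_volatile_shifts() -> dict[str, dict[str, float]]:
    shifts: dict[str, dict[str, float]] = {}
    # four shared differentials; ordering AH-HN-1 > AH-HN-2 > ZJ > HB
    for c in NAMED_VOLATILES:
        shifts[c] = {"AH-HN-1": 9.6, "AH-HN-2": 7.0, "HB": -7.0}
    # differential in both middle-grade contrasts, identical shift so the
    # two middle grades stay indistinguishable on these variables
    for k, i in enumerate(range(5, 14)):          # V05..V13 (9)
        shifts[f"V{i:02d}"] = {"AH-HN-1": _alt(k), "AH-HN-2": _alt(k)}
    # differential only in the ZJ vs HB contrast
    for k, i in enumerate(range(14, 26)):         # V14..V25 (12)
        shifts[f"V{i:02d}"] = {"HB": _alt(k)}
    return shifts


def _default_nonvolatile_shifts() -> dict[str, dict[str, float]]:
    shifts: dict[str, dict[str, float]] = {
        # six shared differentials; lactones track the sensory ordering
        # (higher in ZJ), sugars run opposite (higher in HB)
        "isoatractylode A": {"AH-HN-1": -4.0, "AH-HN-2": -4.5, "HB": -4.5},
        "atractylenolide I": {"AH-HN-1": -4.0, "AH-HN-2": -4.5, "HB": -6.5},
        "β-sitosterol": {"AH-HN-1": 4.5, "AH-HN-2": 4.0, "HB": -4.5},
        "maltose": {"AH-HN-1": 4.0, "AH-HN-2": 4.5, "HB": 5.0},
        "sucrose": {"AH-HN-1": 4.0, "AH-HN-2": 4.5, "HB": 4.5},
        "6,9-dihydroxy-3,3a-dihydro atractylenolide III":
            {"AH-HN-1": -4.5, "AH-HN-2": -4.0, "HB": 4.5},
    }
    for k, i in enumerate(range(7, 13)):          # N07..N12 positive (6)
        shifts[f"N{i:02d}"] = {"AH-HN-1": _alt(k), "AH-HN-2": _alt(k)}
    for k, i in enumerate(range(33, 35)):         # N33..N34 negative (2)
        shifts[f"N{i:02d}"] = {"AH-HN-1": _alt(k), "AH-HN-2": _alt(k)}
    for k, i in enumerate(range(13, 20)):         # N13..N19 positive (7)
        shifts[f"N{i:02d}"] = {"HB": _alt(k)}
    for k, i in enumerate(range(35, 39)):         # N35..N38 negative (4)
        shifts[f"N{i:02d}"] = {"HB": _alt(k)}
    return shifts


DEFAULT_SENSORY_TARGETS = MappingProxyType(
    {"ZJ": 72.0, "AH-HN-1": 70.5, "AH-HN-2": 52.0, "HB": 46.0}
)

DEFAULT_SENSORY_COUPLING = MappingProxyType(
    {"caryophyllene": 1.0, "γ-elemene": 1.0, "aromadendrene": 1.0,
     "atractylenolide I": 1.0}
)


@dataclass(frozen=True)
class EffectSpec:
    """Planted grade effects: the ground truth the pipeline must recover.

    ``*_shifts`` map variable id -> group -> shift in pooled-SD units on
    the log scale (groups absent from the inner map sit at the ZJ
    baseline). A variable is a planted differential for the contrast
    (ZJ vs g) exactly when its shift for g is non-zero. ``effect_scale``
    multiplies every shift (0 gives the no-effect null).
    """

    volatile_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_volatile_shifts)
    nonvolatile_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_nonvolatile_shifts)
    effect_scale: float = 1.0
    enose_informative: tuple[str, ...] = ENOSE_INFORMATIVE
    etongue_informative: tuple[str, ...] = ETONGUE_INFORMATIVE
    enose_loadings: pd.DataFrame = field(default_factory=default_enose_loadings)
    etongue_loadings: pd.DataFrame = field(default_factory=default_etongue_loadings)
    sensory_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENSORY_TARGETS))
    sensory_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENSORY_COUPLING))
    sensory_coupling_scale: float = 1.5   # score points per z-unit

    # ------------------------------------------------------------------
    def shifts(self, platform: str) -> Mapping[str, Mapping[str, float]]:
        return {"volatile": self.volatile_shifts,
                "nonvolatile": self.nonvolatile_shifts}[platform]

    def differential_sets(self, platform: str, reference: str = "ZJ"
                          ) -> dict[str, set[str]]:
        """Planted VIP-screening truth per pairwise contrast vs the reference."""
        out: dict[str, set[str]] = {}
        if self.effect_scale == 0:
            return out
        for var, by_group in self.shifts(platform).items():
            for g, s in by_group.items():
                if s != 0 and g != reference:
                    out.setdefault(f"{reference} vs {g}", set()).add(var)
        return out

    def shared_set(self, platform: str, reference: str = "ZJ") -> set[str]:
        sets = self.differential_sets(platform, reference)
        if not sets:
            return set()
        return set.intersection(*sets.values())

    def union_set(self, platform: str, reference: str = "ZJ") -> set[str]:
        sets = self.differential_sets(platform, reference)
        if not sets:
            return set()
        return set.union(*sets.values())

    def scaled(self, effect_scale: float) -> "EffectSpec":
        return replace(self, effect_scale=effect_scale)

    def grade_axis(self, platform: str) -> Mapping[str, float]:
        """Direction of the middle-grade axis per shared differential.

        The batch-level analytical confound slides batches along this
        axis: +1/-1 per variable shared by all three reference
        contrasts, signed by which middle grade the variable favours.
        """
        out: dict[str, float] = {}
        for var in self.shared_set(platform):
            by_group = self.shifts(platform)[var]
            diff = by_group.get("AH-HN-2", 0.0) - by_group.get("AH-HN-1", 0.0)
            out[var] = float(np.sign(diff)) if diff else 1.0
        return out

    def group_log_means(self, platform: str, panel: CompoundPanel,
                        pooled_sd: float, groups) -> pd.DataFrame:
        """Planted mean log abundances (variables x groups), noise-free."""
        base = panel.base_log_abundance(platform)
        shifts = self.shifts(platform)
        out = pd.DataFrame(
            {g: base.copy() for g in groups}, index=base.index
        )
        for var, by_group in shifts.items():
            if var not in out.index:
                raise ValueError(f"unknown compound id in effect spec: {var!r}")
            for g, s in by_group.items():
                if g in out.columns:
                    out.loc[var, g] += self.effect_scale * s * pooled_sd
        return out


def default_effects() -> EffectSpec:
    return EffectSpec()


# ----------------------------------------------------------------------
# noise
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative (log-normal) noise structure, natural-log scale.

    ``drift_sigma`` — per-acquisition gain factor shared by every sensor
    of an array within one measurement (run-to-run baseline drift);
    compound tables carry no analogous shared factor because they
    represent internal-standard-normalised relative contents, where the
    shared extraction/concentration factor cancels in the ratio;
    ``class_sigma`` — per-acquisition response-factor drift shared by
    the compounds of one chemical class (ionisation/response drift that
    a single internal standard cannot cancel);
    ``batch_sigma`` — per-variable batch-level biological noise of the
    normalised abundances;
    ``replicate_sigma`` — per-variable technical noise per observation
    (compound tables); ``sensor_sigma`` — the analogous per-sensor noise
    of the arrays;
    ``confound_volatile`` / ``confound_nonvolatile`` — batch-level
    analytical confound (sample-preparation variation) sliding each
    batch along the platform's grade axis; the two platforms' confounds
    are independent, which is what makes mid-level fusion genuinely
    better than any single platform.
    ``drift_sigma`` and ``sensor_sigma`` together are calibrated so
    repeated acquisitions of one sample stay below 3% RSD per sensor.
    """

    drift_sigma: float = 0.008
    class_sigma: float = 0.016
    batch_sigma: float = 0.004
    replicate_sigma: float = 0.005
    sensor_sigma: float = 0.009
    confound_volatile: float = 0.037
    confound_nonvolatile: float = 0.011

    def confound_sigma(self, platform: str) -> float:
        return {"volatile": self.confound_volatile,
                "nonvolatile": self.confound_nonvolatile}[platform]

    def validate(self) -> None:
        for name in ("drift_sigma", "class_sigma", "batch_sigma",
                     "replicate_sigma", "sensor_sigma", "confound_volatile",
                     "confound_nonvolatile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def pooled_sd(self) -> float:
        """Within-group SD of replicate-level log values (planted-effect unit)."""
        return float(np.sqrt(self.batch_sigma ** 2 + self.class_sigma ** 2
                             + self.replicate_sigma ** 2))


def default_noise() -> NoiseModel:
    return NoiseModel()
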