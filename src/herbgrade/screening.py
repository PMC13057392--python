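"""Differential screening and correlation mapping.

Workflows mirroring the grading study's chemometric layer:

* internal-standard relative content for chromatographic peak areas;
* pairwise OPLS-DA of each lower grade against the reference group
  (ZJ), VIP > 1 screening, per-contrast differential sets, and their
  union / intersection ("shared differentials");
* multiclass OPLS-DA of the sensor arrays with VIP > 1 sensor
  screening;
* tie-corrected Spearman correlation matrices (sensor vs compound,
  sensory score vs compound) with two-sided t-approximation p-values.

Compound models run on batch-mean rows (replicates averaged); sensor
models run on replicate-level rows. An optional permutation-validity
gate empties the differential set of a model whose label-permutation
p-value exceeds alpha, so null data yields (almost) no flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataMatrix
from .opls import (
    OplsDaModel,
    OplsError,
    fit_opls_da,
    permutation_test,
    vip,
)
from .synthetic import SyntheticDataset

__all__ = [
    "DifferentialSet",
    "CorrelationMatrix",
    "relative_content",
    "screen_differentials",
    "shared_differentials",
    "union_differentials",
    "screen_pairwise",
    "screen_compounds",
    "screen_sensor_array",
    "spearman_matrix",
    "score_compound_correlation",
    "sensor_compound_map",
    "ScreeningResult",
]


# ----------------------------------------------------------------------
# relative content
# ----------------------------------------------------------------------
def relative_content(areas: pd.DataFrame, internal_standard: pd.Series) -> pd.DataFrame:
    """Peak areas divided by the internal-standard area, per observation."""
    internal_standard = pd.Series(internal_standard)
    bad = internal_standard[internal_standard <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive internal-standard area for observation {bad.index[0]!r}"
        )
    return areas.div(internal_standard, axis=0)


# ----------------------------------------------------------------------
# differential sets
# ----------------------------------------------------------------------
@dataclass
class DifferentialSet:
    """Variables flagged VIP > threshold for one comparison."""

    comparison: str
    platform: str
    variables: list[str]
    vips: pd.Series
    valid: bool | None = None        # permutation verdict, None = not gated
    permutation_p: float | None = None

    def __len__(self) -> int:
        return len(self.variables)


def screen_differentials(model: OplsDaModel, threshold: float = 1.0,
                         comparison: str = "", platform: str = "") -> DifferentialSet:
    """Variables with VIP strictly greater than the threshold, descending."""
    scores = vip(model, threshold)
    above = scores.above()
    return DifferentialSet(comparison=comparison, platform=platform,
                           variables=list(above.index), vips=scores.values)


def _same_platform(sets) -> str:
    if not sets:
        raise ValueError("need at least one differential set")
    platforms = {s.platform for s in sets}
    if len(platforms) > 1:
        raise ValueError(f"mixed platforms: {sorted(platforms)}")
    return platforms.pop()


def shared_differentials(sets) -> list[str]:
    """Exact intersection of the sets' variable ids (sorted)."""
    _same_platform(sets)
    common = set(sets[0].variables)
    for s in sets[1:]:
        common &= set(s.variables)
    return sorted(common)


def union_differentials(sets) -> list[str]:
    _same_platform(sets)
    out: set[str] = set()
    for s in sets:
        out |= set(s.variables)
    return sorted(out)


# ----------------------------------------------------------------------
# screening workflows
# ----------------------------------------------------------------------
def _maybe_gate(dm: DataMatrix, dset: DifferentialSet, n_permutations: int,
                n_orthogonal: int, alpha: float, seed: int) -> DifferentialSet:
    if n_permutations <= 0:
        return dset
    blocks = (dm.obs["batch_id"].to_numpy()
              if "batch_id" in dm.obs.columns else None)
    summary = permutation_test(dm, dm.groups, n_permutations=n_permutations,
                               n_orthogonal=n_orthogonal, seed=seed, alpha=alpha,
                               blocks=blocks)
    dset.valid = summary.valid
    dset.permutation_p = summary.p_value
    if not summary.valid:
        dset.variables = []
    return dset


def screen_pairwise(dm: DataMatrix, group_a: str, group_b: str,
                    n_orthogonal: int = 1, threshold: float = 1.0,
                    n_permutations: int = 0, alpha: float = 0.05,
                    seed: int = 0, level: str = "replicate") -> DifferentialSet:
    """VIP > threshold screening of one two-group contrast.

    ``level`` selects the modelling rows: ``"replicate"`` (default,
    matching the replicate-level observation count the classification
    arithmetic implies) or ``"batch"`` (replicates averaged first).
    """
    sub = dm.subset_groups([group_a, group_b])
    if level == "batch":
        sub = sub.batch_means()
    elif level != "replicate":
        raise ValueError(f"unknown level {level!r}")
    model = fit_opls_da(sub, n_orthogonal=n_orthogonal)
    dset = screen_differentials(model, threshold,
                                comparison=f"{group_a} vs {group_b}",
                                platform=dm.platform)
    return _maybe_gate(sub, dset, n_permutations, n_orthogonal, alpha, seed)


@dataclass
class ScreeningResult:
    """Per-contrast differential sets plus their union and intersection."""

    platform: str
    sets: dict[str, DifferentialSet]
    union: list[str]
    shared: list[str]

    def counts_by(self, annotation: pd.Series) -> pd.Series:
        """Union counts grouped by a variable annotation (e.g. ion mode)."""
        return annotation.loc[self.union].value_counts()


def screen_compounds(dataset_or_dm, platform: str = "volatile",
                     reference: str = "ZJ", by_ion_mode: bool = False,
                     n_orthogonal: int = 1, threshold: float = 1.0,
                     n_permutations: int = 0, alpha: float = 0.05,
                     seed: int = 0, level: str = "replicate") -> ScreeningResult:
    """Screen every pairwise contrast of the reference group vs the others.

    By default a single model covers the whole variable panel per
    contrast; per-ion-mode union counts come from the variable
    annotation (``ScreeningResult.counts_by``). With ``by_ion_mode``
    positive- and negative-mode variables are modelled separately per
    contrast — as the two ESI acquisitions would be — and each
    contrast's set is the union over modes.
    """
    dm = (dataset_or_dm.platform(platform)
          if isinstance(dataset_or_dm, SyntheticDataset) else dataset_or_dm)
    groups = [g for g in pd.unique(dm.obs["group"]) if g != reference]
    sets: dict[str, DifferentialSet] = {}
    for g in groups:
        label = f"{reference} vs {g}"
        if by_ion_mode:
            parts = []
            for mode in pd.unique(dm.var["ion_mode"]):
                ids = dm.var.index[dm.var["ion_mode"] == mode]
                parts.append(screen_pairwise(dm.select_vars(ids), reference, g,
                                             n_orthogonal, threshold,
                                             n_permutations, alpha, seed, level))
            merged = DifferentialSet(
                comparison=label, platform=dm.platform,
                variables=union_differentials(parts),
                vips=pd.concat([p.vips for p in parts]),
                valid=(None if parts[0].valid is None
                       else all(p.valid for p in parts)),
            )
            sets[label] = merged
        else:
            sets[label] = screen_pairwise(dm, reference, g, n_orthogonal,
                                          threshold, n_permutations, alpha,
                                          seed, level)
    all_sets = list(sets.values())
    return ScreeningResult(platform=dm.platform, sets=sets,
                           union=union_differentials(all_sets),
                           shared=shared_differentials(all_sets))


def screen_sensor_array(dataset_or_dm, platform: str = "enose",
                        n_orthogonal: int = 1, threshold: float = 1.0,
                        n_permutations: int = 0, alpha: float = 0.05,
                        seed: int = 0) -> DifferentialSet:
    """Multiclass (all-grades) OPLS-DA sensor screening at replicate level."""
    dm = (dataset_or_dm.platform(platform)
          if isinstance(dataset_or_dm, SyntheticDataset) else dataset_or_dm)
    model = fit_opls_da(dm, n_orthogonal=n_orthogonal)
    dset = screen_differentials(model, threshold, comparison="all grades",
                                platform=dm.platform)
    return _maybe_gate(dm, dset, n_permutations, n_orthogonal, alpha, seed)


# ----------------------------------------------------------------------
# Spearman correlation
# ----------------------------------------------------------------------
@dataclass
class CorrelationMatrix:
    """Spearman rho / p-value matrices with a significance mask."""

    rho: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame
    alpha: float


def spearman_matrix(A: pd.DataFrame, B: pd.DataFrame | None = None,
                    alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman correlations between columns of A and B.

    Uses average ranks (tie-corrected) with the two-sided t
    approximation for p-values. Constant columns give NaN (undefined),
    never zero. With ``B`` omitted, the self-correlation block of A is
    returned (symmetric, unit diagonal).
    """
    if B is None:
        B = A
    else:
        if len(A) != len(B):
            raise ValueError("A and B must be row-aligned")
    if len(A) < 3:
        raise ValueError("need at least 3 observations")
    rho = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    p = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    const_a = {c: A[c].nunique() <= 1 for c in A.columns}
    const_b = {c: B[c].nunique() <= 1 for c in B.columns}
    for ca in A.columns:
        for cb in B.columns:
            if const_a[ca] or const_b[cb]:
                continue  # undefined, stays NaN
            r, pv = stats.spearmanr(A[ca], B[cb])
            rho.loc[ca, cb] = r
            p.loc[ca, cb] = pv
    mask = p < alpha
    return CorrelationMatrix(rho=rho, p=p, mask=mask, alpha=alpha)


def score_compound_correlation(dataset: SyntheticDataset,
                               weights=None, compounds=None,
                               alpha: float = 0.05) -> CorrelationMatrix:
    """Spearman map of batch sensory scores against compound levels.

    Scores are computed from the evaluator counts with the default
    strict-ranking criterion weights; compounds default to the union of
    both platforms' planted shared differentials.
    """
    from .sensory import (PairwiseComparison, batch_scores,
                          binary_comparison_weights)
    from .synthetic import CRITERIA

    if weights is None:
        weights = binary_comparison_weights(PairwiseComparison.from_ranking(CRITERIA))
    scores = batch_scores(dataset.evaluator_counts, weights).set_index("batch_id")
    frames = []
    for platform in ("volatile", "nonvolatile"):
        bm = dataset.platform(platform).batch_means()
        tab = bm.to_table().set_index("batch_id")
        frames.append(tab[bm.var_ids])
    levels = pd.concat(frames, axis=1).loc[scores.index]
    if compounds is None:
        compounds = sorted(dataset.truth.shared_set("volatile")
                           | dataset.truth.shared_set("nonvolatile"))
    return spearman_matrix(scores[["score"]], levels[list(compounds)], alpha)


def sensor_compound_map(dataset: SyntheticDataset, sensor_platform: str,
                        compound_platform: str, sensors=None, compounds=None,
                        alpha: float = 0.05) -> CorrelationMatrix:
    """Spearman map between flagged sensors and compounds at batch level."""
    sens = dataset.platform(sensor_platform).batch_means()
    comp = dataset.platform(compound_platform).batch_means()
    s_tab = sens.to_table().set_index("batch_id")
    c_tab = comp.to_table().set_index("batch_id")
    sensors = list(sensors) if sensors is not None else sens.var_ids
    compounds = list(compounds) if compounds is not None else comp.var_ids
    return spearman_matrix(s_tab[sensors], c_tab.loc[s_tab.index, compounds], alpha)
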