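"""Fuzzy-mathematics comprehensive sensory evaluation.

A panel of trained evaluators rates each batch on four appearance
criteria (sectional color, chrysanthemum pattern, number of oil spots,
number per kilogram), each divided into four quality levels. The score
combines:

* criterion weights ``w`` from the binary-comparison method — every
  pair of criteria is compared, the more important one scoring 1 and
  the other 0, and each criterion's weight is its total score divided
  by the sum of all scores (with the self-comparison diagonal set to 1,
  so a strict ranking over four criteria yields weights 4:3:2:1);
* a membership-degree matrix ``M`` whose entry (i, j) is the fraction
  of evaluators assigning level j on criterion i;
* level values ``V`` (defaults 90/70/50/30, the centres of 20-point
  bands).

The batch score is the weighted average ``B = w · M · V``, banded into
grades (60-80 Grade I, 40-60 Grade II by default; bands are
lower-closed, upper-open, topmost band closed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseComparison",
    "CriterionWeights",
    "MembershipMatrix",
    "LevelValues",
    "SensoryResult",
    "binary_comparison_weights",
    "membership_matrix",
    "fuzzy_score",
    "classify_grade",
    "batch_scores",
    "DEFAULT_BANDS",
    "OUT_OF_RANGE",
]

DEFAULT_CRITERIA = ("sectional color", "chrysanthemum pattern", "oil spots",
                    "number per kilogram")
DEFAULT_BANDS = (("Grade I", 60.0, 80.0), ("Grade II", 40.0, 60.0))
OUT_OF_RANGE = "out-of-range"


@dataclass
class PairwiseComparison:
    """0/1 wins matrix over criteria; diagonal is 1 by convention."""

    criteria: tuple[str, ...]
    wins: np.ndarray

    def __post_init__(self):
        self.wins = np.asarray(self.wins, dtype=float)
        n = len(self.criteria)
        if self.wins.shape != (n, n):
            raise ValueError("wins matrix shape must match the criteria list")
        if not np.allclose(np.diag(self.wins), 1.0):
            raise ValueError("diagonal of the wins matrix must be 1")
        for i in range(n):
            for j in range(i + 1, n):
                if self.wins[i, j] + self.wins[j, i] != 1:
                    raise ValueError(
                        "invalid comparison between "
                        f"{self.criteria[i]!r} and {self.criteria[j]!r}: "
                        "exactly one side must score 1"
                    )

    @classmethod
    def from_ranking(cls, criteria) -> "PairwiseComparison":
        """Strict importance ranking, most important first."""
        n = len(criteria)
        wins = np.tril(np.ones((n, n)))
        wins = wins.T  # row i beats all later criteria
        np.fill_diagonal(wins, 1.0)
        return cls(tuple(criteria), wins)


@dataclass
class CriterionWeights:
    criteria: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class MembershipMatrix:
    """Criteria x levels evaluator fractions; every row sums to 1."""

    criteria: tuple[str, ...]
    M: np.ndarray
    panel_size: int

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if ((self.M < 0) | (self.M > 1)).any():
            raise ValueError("membership degrees must lie in [0, 1]")
        if not np.allclose(self.M.sum(axis=1), 1.0):
            raise ValueError("each criterion's memberships must sum to 1")


@dataclass
class LevelValues:
    V: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if not np.all(np.diff(self.V) < 0):
            raise ValueError("level values must be strictly decreasing")


@dataclass
class SensoryResult:
    score: float
    grade: str


def binary_comparison_weights(pc: PairwiseComparison) -> CriterionWeights:
    """Weights as row sums of the wins matrix over the total score."""
    totals = pc.wins.sum(axis=1)
    return CriterionWeights(pc.criteria, totals / totals.sum())


def membership_matrix(counts, panel_size: int,
                      criteria=None) -> MembershipMatrix:
    """Evaluator fractions per criterion and level.

    ``counts`` is a criteria x levels array of non-negative integers;
    each row must sum to ``panel_size``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    sums = counts.sum(axis=1)
    bad = np.nonzero(sums != panel_size)[0]
    if bad.size:
        raise ValueError(
            f"criterion {bad[0]} counts sum to {int(sums[bad[0]])}, "
            f"expected panel size {panel_size}"
        )
    criteria = tuple(criteria) if criteria is not None else tuple(
        f"criterion-{i + 1}" for i in range(counts.shape[0])
    )
    return MembershipMatrix(criteria, counts / panel_size, panel_size)


def fuzzy_score(w: CriterionWeights, M: MembershipMatrix, V: LevelValues,
                bands=DEFAULT_BANDS) -> SensoryResult:
    """Weighted sensory score ``B = sum_i w_i sum_j M_ij V_j`` with its band."""
    if len(w.w) != M.M.shape[0]:
        raise ValueError(
            f"{len(w.w)} weights but {M.M.shape[0]} membership rows"
        )
    if M.M.shape[1] != len(V.V):
        raise ValueError(
            f"{M.M.shape[1]} membership levels but {len(V.V)} level values"
        )
    score = float(w.w @ (M.M @ V.V))
    return SensoryResult(score, classify_grade(score, bands))


def classify_grade(score: float, bands=DEFAULT_BANDS) -> str:
    """Band a score: lower-closed, upper-open; topmost band upper-closed.

    Scores covered by no band get the explicit ``OUT_OF_RANGE`` label
    rather than being clamped.
    """
    ordered = sorted(bands, key=lambda b: -b[2])
    for k, (label, lo, hi) in enumerate(ordered):
        if lo <= score < hi or (k == 0 and score == hi):
            return label
    return OUT_OF_RANGE


def batch_scores(counts_table: pd.DataFrame, weights: CriterionWeights,
                 level_values: LevelValues | None = None,
                 panel_size: int | None = None,
                 bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Score every batch of a long-format evaluator-counts table.

    Expects columns batch_id, criterion, level, count; panel size is
    inferred per batch when not given. Returns one row per batch with
    the fuzzy score and grade band.
    """
    V = level_values or LevelValues(np.array([90.0, 70.0, 50.0, 30.0]))
    required = {"batch_id", "criterion", "level", "count"}
    missing = required - set(counts_table.columns)
    if missing:
        raise ValueError(f"missing column: {sorted(missing)[0]!r}")
    rows = []
    for batch_id, sub in counts_table.groupby("batch_id", sort=False):
        wide = (sub.pivot_table(index="criterion", columns="level",
                                values="count", aggfunc="sum")
                .reindex(list(weights.criteria)))
        if wide.isna().any().any():
            raise ValueError(f"batch {batch_id!r} is missing criterion counts")
        counts = wide.to_numpy()
        size = panel_size if panel_size is not None else int(counts[0].sum())
        M = membership_matrix(counts, size, criteria=weights.criteria)
        res = fuzzy_score(weights, M, V, bands)
        rows.append({"batch_id": batch_id, "score": res.score,
                     "grade_band": res.grade})
    return pd.DataFrame(rows)
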