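"""Shared tabular container for feature matrices.

Every measurement platform is represented as a :class:`DataMatrix`: a
dense observations x variables block plus row metadata (batch identity,
specification group, grade, replicate index) and column metadata
(variable id, platform, ion mode where applicable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns required in every on-disk feature table
META_COLUMNS = ("batch_id", "group", "grade", "replicate")


@dataclass
class DataMatrix:
    """Observations x variables feature block with aligned metadata.

    Parameters
    ----------
    X
        Numeric matrix, one row per observation.
    obs
        Row metadata; must contain at least ``batch_id`` and ``group``.
    var
        Column metadata indexed by variable id (unique).
    platform
        Free-form platform tag (``volatile``, ``nonvolatile``, ``enose``,
        ``etongue`` for the built-in study design).
    """

    X: np.ndarray
    obs: pd.DataFrame
    var: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.obs) != self.X.shape[0]:
            raise ValueError(
                f"obs has {len(self.obs)} rows but X has {self.X.shape[0]}"
            )
        if len(self.var) != self.X.shape[1]:
            raise ValueError(
                f"var has {len(self.var)} rows but X has {self.X.shape[1]} columns"
            )
        if self.var.index.has_duplicates:
            dup = self.var.index[self.var.index.duplicated()][0]
            raise ValueError(f"duplicate variable id: {dup!r}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_var(self) -> int:
        return self.X.shape[1]

    @property
    def var_ids(self) -> list[str]:
        return list(self.var.index)

    @property
    def groups(self) -> np.ndarray:
        return self.obs["group"].to_numpy()

    # ------------------------------------------------------------------
    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        platform: str = "",
        meta_columns: tuple[str, ...] = META_COLUMNS,
    ) -> "DataMatrix":
        """Build from a flat table whose leading columns are metadata."""
        missing = [c for c in meta_columns if c not in table.columns]
        if missing:
            raise ValueError(f"missing metadata column: {missing[0]!r}")
        obs = table.loc[:, list(meta_columns)].reset_index(drop=True)
        feat = table.drop(columns=list(meta_columns))
        var = pd.DataFrame(index=pd.Index(feat.columns, name="variable"))
        var["platform"] = platform
        return cls(feat.to_numpy(dtype=float), obs, var, platform)

    def to_table(self) -> pd.DataFrame:
        """Flatten to a single table (metadata columns first)."""
        out = self.obs.reset_index(drop=True).copy()
        feat = pd.DataFrame(self.X, columns=self.var.index)
        return pd.concat([out, feat.reset_index(drop=True)], axis=1)

    # ------------------------------------------------------------------
    def select_vars(self, ids) -> "DataMatrix":
        idx = [self.var.index.get_loc(v) for v in ids]
        return DataMatrix(
            self.X[:, idx], self.obs.copy(), self.var.iloc[idx].copy(), self.platform
        )

    def subset_groups(self, groups) -> "DataMatrix":
        mask = self.obs["group"].isin(list(groups)).to_numpy()
        return DataMatrix(
            self.X[mask], self.obs.loc[mask].reset_index(drop=True), self.var.copy(),
            self.platform,
        )

    def batch_means(self) -> "DataMatrix":
        """Average replicate observations within each batch.

        Returns a batch-level matrix (one row per batch, replicate
        column dropped), preserving first-appearance batch order.
        """
        obs = self.obs.reset_index(drop=True)
        order = pd.unique(obs["batch_id"])
        rows = []
        meta = []
        for b in order:
            mask = (obs["batch_id"] == b).to_numpy()
            rows.append(self.X[mask].mean(axis=0))
            first = obs.loc[mask].iloc[0]
            meta.append({c: first[c] for c in obs.columns if c != "replicate"})
        return DataMatrix(
            np.vstack(rows), pd.DataFrame(meta), self.var.copy(), self.platform
        )

    def check_aligned(self, other: "DataMatrix") -> None:
        """Raise if row identities differ, naming the first mismatch."""
        a = self.obs
        b = other.obs
        if len(a) != len(b):
            raise ValueError(
                f"row count mismatch: {len(a)} vs {len(b)} observations"
            )
        keys = [k for k in ("batch_id", "replicate") if k in a.columns and k in b.columns]
        for i in range(len(a)):
            for k in keys:
                if a[k].iloc[i] != b[k].iloc[i]:
                    raise ValueError(
                        f"misaligned observation at row {i}: "
                        f"{k}={a[k].iloc[i]!r} vs {b[k].iloc[i]!r}"
                    )
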