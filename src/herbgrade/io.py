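"""Readers and writers for the on-disk table formats.

All tables are UTF-8 CSV/TSV with a header row; feature tables carry
the metadata columns batch_id, group, grade, replicate followed by
variable columns. Greek letters in compound names are preserved
verbatim. The delimiter is sniffed from the header line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DataMatrix, META_COLUMNS
from .synthetic import SyntheticDataset

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_evaluator_counts",
    "write_evaluator_counts",
    "write_dataset",
    "effects_to_json",
]


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if header.count("\t") > header.count(",") else ","


def read_feature_table(path, platform: str = "") -> DataMatrix:
    """Read a platform feature table (CSV or TSV, sniffed).

    Rejects missing metadata columns (naming the column), duplicate
    (batch_id, replicate) keys, and non-numeric feature cells (naming
    the row and column).
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing metadata column: {missing[0]!r}")
    dup = table.duplicated(subset=["batch_id", "replicate"])
    if dup.any():
        row = table.loc[dup, ["batch_id", "replicate"]].iloc[0]
        raise ValueError(
            f"duplicate observation key (batch_id={row['batch_id']!r}, "
            f"replicate={row['replicate']!r})"
        )
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    for c in feat_cols:
        coerced = pd.to_numeric(table[c], errors="coerce")
        bad = coerced.isna() & table[c].notna()
        if bad.any() or coerced.isna().any():
            i = int(np.nonzero(coerced.isna().to_numpy())[0][0])
            raise ValueError(f"non-numeric value at row {i}, column {c!r}")
        table[c] = coerced
    return DataMatrix.from_table(table, platform=platform)


def write_feature_table(dm: DataMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dm.to_table().to_csv(path, index=False)
    return path


def read_evaluator_counts(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_delimiter(path))
    for c in ("batch_id", "criterion", "level", "count"):
        if c not in table.columns:
            raise ValueError(f"missing column: {c!r}")
    return table


def write_evaluator_counts(counts: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, index=False)
    return path


def effects_to_json(effects) -> str:
    """Serialise the planted ground truth (sets and shifts) to JSON."""
    payload = {
        "effect_scale": effects.effect_scale,
        "volatile_shifts": {k: dict(v) for k, v in effects.volatile_shifts.items()},
        "nonvolatile_shifts": {k: dict(v) for k, v in effects.nonvolatile_shifts.items()},
        "enose_informative": list(effects.enose_informative),
        "etongue_informative": list(effects.etongue_informative),
        "sensory_targets": dict(effects.sensory_targets),
        "sensory_coupling": dict(effects.sensory_coupling),
        "differential_sets": {
            platform: {k: sorted(v) for k, v in
                       effects.differential_sets(platform).items()}
            for platform in ("volatile", "nonvolatile")
        },
    }
    return json.dumps(payload, ensure_ascii=False, indent=2)


def write_dataset(dataset: SyntheticDataset, out_dir) -> list[Path]:
    """Write the four platform CSVs, evaluator counts, and the truth record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, dm in dataset.tables().items():
        written.append(write_feature_table(dm, out_dir / f"{name}.csv"))
    written.append(write_evaluator_counts(dataset.evaluator_counts,
                                          out_dir / "evaluator_counts.csv"))
    truth = out_dir / "truth.json"
    truth.write_text(effects_to_json(dataset.truth), encoding="utf-8")
    written.append(truth)
    return written
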