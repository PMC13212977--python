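"""Drug response (ln IC50) ingestion, deduplication, merging and unit handling.

Responses are (cell_id, drug_id, ln IC50 in micromolar) records.  Replicate
measurements of the same pair are averaged; on overlap between the GDSC1 and
GDSC2 screens the GDSC2 value wins (it covers a wider concentration range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DedupStats",
    "ResponseTable",
    "average_duplicates",
    "merge_gdsc",
    "convert_external_ic50",
    "filter_capped",
]

_COLUMNS = ["cell_id", "drug_id", "ln_ic50", "source"]
_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "M": 1e6}


@dataclass
class DedupStats:
    """Summary of duplicate averaging.

    ``rmsd`` and ``pcc`` compare each duplicated value against its group mean
    (one scalar per table): the RMSD of deviations, and the Pearson
    correlation between the raw duplicate values and their repeated means.
    """

    n_duplicate_values: int = 0
    n_groups_averaged: int = 0
    rmsd: float = float("nan")
    pcc: float = float("nan")


@dataclass
class ResponseTable:
    """Deduplicated (cell, drug) -> ln IC50 records with provenance."""

    records: pd.DataFrame
    dedup_stats: DedupStats = field(default_factory=DedupStats)

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"response records missing columns {sorted(missing)}")
        if not np.isfinite(self.records["ln_ic50"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite ln_ic50 values")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cells(self) -> list[str]:
        return sorted(self.records["cell_id"].unique())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug_id"].unique())


def average_duplicates(records: pd.DataFrame) -> ResponseTable:
    """Collapse replicate (cell, drug) measurements to their arithmetic mean.

    Populates dedup statistics over the duplicated values: their count, the
    RMSD of each value from its group mean, and the Pearson correlation of
    values against their repeated group means.
    """
    df = records.copy()
    if "source" not in df.columns:
        df["source"] = "SYNTHETIC"
    df = df[_COLUMNS]
    grouped = df.groupby(["cell_id", "drug_id"], sort=True)
    means = grouped.agg(
        ln_ic50=("ln_ic50", "mean"), source=("source", "first"), n=("ln_ic50", "size")
    ).reset_index()

    sizes = grouped["ln_ic50"].transform("size")
    dup_mask = sizes > 1
    stats = DedupStats(
        n_duplicate_values=int(dup_mask.sum()),
        n_groups_averaged=int((means["n"] > 1).sum()),
    )
    if dup_mask.any():
        vals = df.loc[dup_mask, "ln_ic50"].to_numpy(dtype=float)
        grp_means = grouped["ln_ic50"].transform("mean")[dup_mask].to_numpy(dtype=float)
        stats.rmsd = float(np.sqrt(np.mean((vals - grp_means) ** 2)))
        if np.std(vals) > 0 and np.std(grp_means) > 0:
            stats.pcc = float(np.corrcoef(vals, grp_means)[0, 1])
        else:
            stats.pcc = 1.0 if np.allclose(vals, grp_means) else float("nan")
    return ResponseTable(means.drop(columns="n"), dedup_stats=stats)


def merge_gdsc(g1: ResponseTable, g2: ResponseTable) -> ResponseTable:
    """Union of two deduplicated screens with second-screen (GDSC2) priority.

    Pairs present in both tables keep the ``g2`` value and are tagged GDSC2.
    """
    a = g1.records.set_index(["cell_id", "drug_id"])
    b = g2.records.set_index(["cell_id", "drug_id"])
    for tbl, name in ((a, "g1"), (b, "g2")):
        if tbl.index.has_duplicates:
            raise ValueError(f"{name} is not deduplicated")
    only_a = a.loc[~a.index.isin(b.index)]
    merged = pd.concat([only_a, b]).reset_index()
    merged = merged.sort_values(["cell_id", "drug_id"], kind="stable").reset_index(drop=True)
    return ResponseTable(merged[_COLUMNS])


def convert_external_ic50(value: float, unit: str) -> float:
    """Convert a raw IC50 measurement to ln(IC50 in micromolar)."""
    if unit not in _UNIT_TO_UM:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_TO_UM)}")
    if not (value > 0):
        raise ValueError(f"IC50 must be positive, got {value}")
    return math.log(value * _UNIT_TO_UM[unit])


def filter_capped(
    records: pd.DataFrame | ResponseTable, cap_value_um: float, atol: float = 1e-9
) -> ResponseTable:
    """Drop records whose raw IC50 sits exactly at the assay cap (in uM).

    Capped values are censoring artifacts, not measurements; they are removed
    before per-entity statistics.  The removed count is available on the
    returned table as ``n_capped_removed``.
    """
    df = records.records if isinstance(records, ResponseTable) else records
    if cap_value_um <= 0:
        raise ValueError("cap must be positive (uM)")
    ln_cap = math.log(cap_value_um)
    keep = ~np.isclose(df["ln_ic50"].to_numpy(dtype=float), ln_cap, atol=atol)
    out = ResponseTable(df.loc[keep].reset_index(drop=True))
    out.n_capped_removed = int((~keep).sum())  # type: ignore[attr-defined]
    return out
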