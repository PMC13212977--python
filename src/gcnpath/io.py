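"""Readers and writers for the plain-text formats used across the pipeline.

All tabular formats are pandas round-trips; gene sets use GMT; networks use
2- or 3-column edge lists (STRING-style 0-1000 scores are auto-scaled to
[0, 1]).  Every reader is gzip-transparent via pandas/Python's own handling
of ``.gz`` suffixes.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "read_drug_table",
    "read_response_gdsc",
    "read_response_chembl",
    "read_response_tsv",
    "write_response_tsv",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), with free-text provenance.

    Pathway order is the insertion order of ``sets`` and is treated as
    canonical by every downstream artifact (score matrices, PCN graphs).
    """

    sets: dict[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict_to(self, genes: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets falling below ``min_size``."""
        universe = set(genes)
        kept = {}
        for name, members in self.sets.items():
            survivors = members & universe
            if len(survivors) >= min_size:
                kept[name] = survivors
        if not kept:
            raise ValueError("no gene set retains any gene after restriction")
        return GeneSetCollection(kept, provenance=self.provenance)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_gmt(path: str | Path, normalize_ids: bool = False) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> gene ...)."""
    sets: dict[str, frozenset[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate pathway id {name!r} in GMT")
            genes = [g.strip() for g in parts[2:] if g.strip()]
            if normalize_ids:
                genes = [g.upper() for g in genes]
            sets[name] = frozenset(genes)
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited matrix: first column row ids, header row sample ids."""
    if sep is None:
        sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate row identifiers in matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate column identifiers in matrix")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep)


def read_edge_list(
    path: str | Path,
    min_confidence: float | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a 2- or 3-column gene network edge list.

    Returns a DataFrame with columns ``source, target, confidence``.  A third
    numeric column is taken as confidence; values above 1 are assumed to be
    STRING-style 0-1000 scores and divided by 1000.  Self-loops and duplicate
    undirected edges are removed.
    """
    df = pd.read_csv(path, sep=sep or r"\s+", header=None, comment="#", engine="python")
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    # tolerate a header row of non-numeric labels in 3-column files
    if df.shape[1] >= 3 and not pd.api.types.is_numeric_dtype(df.iloc[:, 2]):
        try:
            pd.to_numeric(df.iloc[1:, 2])
            df = df.iloc[1:].reset_index(drop=True)
        except (ValueError, TypeError):
            pass
    out = pd.DataFrame(
        {
            "source": df.iloc[:, 0].astype(str),
            "target": df.iloc[:, 1].astype(str),
        }
    )
    if df.shape[1] >= 3:
        conf = pd.to_numeric(df.iloc[:, 2], errors="coerce").astype(float)
        if conf.max() > 1.0:
            conf = conf / 1000.0
        out["confidence"] = conf.values
    else:
        out["confidence"] = 1.0
    out = out[out["source"] != out["target"]]
    if min_confidence is not None:
        out = out[out["confidence"] >= min_confidence]
    key = out.apply(lambda r: tuple(sorted((r["source"], r["target"]))), axis=1)
    out = out.loc[~key.duplicated()].reset_index(drop=True)
    return out


def read_drug_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a drug table with columns drug_id, [cid,] smiles."""
    if sep is None:
        sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "drug_id" not in cols or "smiles" not in cols:
        raise ValueError("drug table must have drug_id and smiles columns")
    out = pd.DataFrame(
        {
            "drug_id": df[cols["drug_id"]].astype(str),
            "smiles": df[cols["smiles"]].astype(str),
        }
    )
    out["cid"] = df[cols["cid"]] if "cid" in cols else None
    if out["drug_id"].duplicated().any():
        dupes = out.loc[out["drug_id"].duplicated(), "drug_id"].tolist()
        raise ValueError(f"duplicate drug_id values: {dupes}")
    return out


_GDSC_CELL_COLS = ("SANGER_MODEL_ID", "COSMIC_ID", "CELL_LINE_NAME", "cell_id")
_GDSC_DRUG_COLS = ("DRUG_ID", "DRUG_NAME", "drug_id")


def read_response_gdsc(path: str | Path, source: str = "GDSC2") -> pd.DataFrame:
    """Read a GDSC-dialect drug response CSV into (cell_id, drug_id, ln_ic50, source)."""
    df = pd.read_csv(path)
    cell_col = next((c for c in _GDSC_CELL_COLS if c in df.columns), None)
    drug_col = next((c for c in _GDSC_DRUG_COLS if c in df.columns), None)
    val_col = next((c for c in ("LN_IC50", "ln_ic50") if c in df.columns), None)
    if cell_col is None or drug_col is None or val_col is None:
        raise ValueError("not a recognizable GDSC response table")
    return pd.DataFrame(
        {
            "cell_id": df[cell_col].astype(str),
            "drug_id": df[drug_col].astype(str),
            "ln_ic50": df[val_col].astype(float),
            "source": source,
        }
    )


def read_response_chembl(path: str | Path) -> pd.DataFrame:
    """Read a ChEMBL activity export (IC50 rows only) into canonical ln(uM) records.

    Rows with non-positive values or units other than nM/uM/M are dropped.
    """
    import numpy as np

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"missing column, one of {names}")

    typ = df[col("standard_type")].astype(str)
    df = df[typ.str.upper() == "IC50"]
    unit_scale = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "M": 1e6}
    units = df[col("standard_units")].astype(str)
    vals = pd.to_numeric(df[col("standard_value")], errors="coerce")
    scale = units.map(unit_scale)
    ok = vals.notna() & (vals > 0) & scale.notna()
    df, vals, scale = df[ok], vals[ok], scale[ok]
    return pd.DataFrame(
        {
            "cell_id": df[col("cell_id", "cell_chembl_id")].astype(str).values,
            "drug_id": df[col("drug_id", "molecule_chembl_id")].astype(str).values,
            "ln_ic50": np.log(vals.values * scale.values),
            "source": "CHEMBL",
        }
    )


def read_response_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "drug_id": str})
    missing = {"cell_id", "drug_id", "ln_ic50"} - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "SYNTHETIC"
    return df


def write_response_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
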