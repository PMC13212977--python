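"""Gene expression normalization, pathway activity scoring, and robust scaling.

Cell lines are represented not by their gene expression vectors but by
per-sample pathway activity scores.  Rank-based single-sample scorers (GSVA,
ssGSEA, singscore) are insensitive to monotone per-sample distortions and
thereby absorb much of the batch effect between expression datasets.

Scores are standardized per pathway with a median/IQR robust scaler and
capped at ``|z| <= 10`` before entering the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSetCollection

__all__ = [
    "normalize_expression",
    "score_pathways",
    "singscore",
    "fit_scaler",
    "apply_scaler",
    "ScalerState",
]

NormMethod = Literal["log2_pc1", "arcsinh", "z_sample", "z_gene", "none"]
ScoreMethod = Literal["gsva", "ssgsea", "ssgsea_nonorm", "singscore"]


def normalize_expression(raw: pd.DataFrame, method: NormMethod = "log2_pc1") -> pd.DataFrame:
    """Normalize a genes x samples expression matrix.

    ``log2_pc1``: log2(x + 1); ``arcsinh``: asinh(x); ``z_sample``: standardize
    each sample column (population sd); ``z_gene``: standardize each gene row
    across samples (constant rows become zeros, with a warning); ``none``:
    identity.
    """
    values = raw.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    if method in ("log2_pc1", "arcsinh") and (values < 0).any():
        raise ValueError(f"negative expression values not allowed under {method}")
    if method == "log2_pc1":
        out = np.log2(values + 1.0)
    elif method == "arcsinh":
        out = np.arcsinh(values)
    elif method == "z_sample":
        mu = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        out = (values - mu) / sd
    elif method == "z_gene":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        constant = (sd == 0).ravel()
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene rows set to zero under z_gene",
                stacklevel=2,
            )
        sd = np.where(sd == 0, 1.0, sd)
        out = (values - mu) / sd
        out[constant, :] = 0.0
    elif method == "none":
        out = values.copy()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def singscore(expr: pd.DataFrame, sets: GeneSetCollection) -> pd.DataFrame:
    """Rank-based single-sample pathway score in [-0.5, 0.5].

    Genes are ranked 1..N per sample ascending (ties receive average ranks).
    For a set of n genes with mean rank m, the minimum possible mean rank is
    (n+1)/2 and the maximum is N-(n-1)/2; the score is the min-max normalized
    mean rank centered at zero:

        score = (m - (n + 1) / 2) / (N - n) - 0.5

    +0.5 means the set occupies the top n ranks, -0.5 the bottom n.
    """
    genes = expr.index.to_numpy()
    n_total = len(genes)
    ranks = np.apply_along_axis(rankdata, 0, expr.to_numpy(dtype=float))
    index_of = {g: i for i, g in enumerate(genes)}
    rows = []
    ids = []
    for name, members in sets.sets.items():
        idx = [index_of[g] for g in members if g in index_of]
        if not idx:
            continue
        n = len(idx)
        m = ranks[idx, :].mean(axis=0)
        if n_total == n:  # every gene in the set: score undefined, center at 0
            rows.append(np.zeros(expr.shape[1]))
        else:
            rows.append((m - (n + 1) / 2.0) / (n_total - n) - 0.5)
        ids.append(name)
    if not rows:
        raise ValueError("no gene set overlaps the expression matrix")
    return pd.DataFrame(np.vstack(rows), index=ids, columns=expr.columns)


def _gseapy_scores(expr: pd.DataFrame, sets: GeneSetCollection, method: str) -> pd.DataFrame:
    import gseapy

    gene_sets = {k: sorted(v) for k, v in sets.sets.items()}
    if method == "gsva":
        res = gseapy.gsva(data=expr, gene_sets=gene_sets, outdir=None, verbose=False)
    else:
        res = gseapy.ssgsea(
            data=expr,
            gene_sets=gene_sets,
            outdir=None,
            sample_norm_method="rank",
            correl_norm_type="rank" if method == "ssgsea" else "zscore",
            no_plot=True,
            verbose=False,
        )
    long = res.res2d
    score_col = "ES" if method == "ssgsea_nonorm" or "NES" not in long.columns else "NES"
    if method == "gsva":
        score_col = "ES"
    wide = long.pivot(index="Term", columns="Name", values=score_col)
    wide = wide.astype(float)
    # restore the collection's pathway order and the expression sample order
    order = [p for p in sets.pathway_ids if p in wide.index]
    return wide.loc[order, expr.columns]


def score_pathways(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    method: ScoreMethod = "gsva",
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Compute a pathways x samples activity score matrix.

    ``gsva`` and ``ssgsea`` delegate to gseapy; ``singscore`` is the built-in
    rank scorer.  Sets are first intersected with the expression genes; sets
    shrinking below ``min_set_size`` genes are dropped with a warning.
    """
    surviving = {}
    for name, members in sets.sets.items():
        hits = members & set(expr.index)
        if len(hits) >= max(1, min_set_size):
            surviving[name] = hits
    dropped = len(sets) - len(surviving)
    if not surviving:
        raise ValueError("no gene set overlaps the expression matrix")
    if dropped:
        warnings.warn(f"dropped {dropped} gene sets with <{min_set_size} genes in data", stacklevel=2)
    reduced = GeneSetCollection(surviving, provenance=sets.provenance)

    if method == "singscore":
        return singscore(expr, reduced)
    if method == "gsva" and expr.shape[1] < 2:
        raise ValueError("gsva needs at least 2 samples (population-relative ranking)")
    if method in ("gsva", "ssgsea", "ssgsea_nonorm"):
        return _gseapy_scores(expr, reduced, method)
    raise ValueError(f"unknown scoring method {method!r}")


@dataclass
class ScalerState:
    """Per-pathway robust scaling parameters (median center, IQR scale).

    Pathways with zero IQR receive scale 1.0 so that the pathway order stays
    aligned with the PCN node order; their ids are kept in ``degenerate``.
    """

    center: dict[str, float]
    scale: dict[str, float]
    cap: float = 10.0
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        for p, s in self.scale.items():
            if s <= 0:
                raise ValueError(f"non-positive scale for pathway {p!r}")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cap": self.cap,
            "pathways": {
                p: {"center": self.center[p], "scale": self.scale[p]} for p in self.center
            },
            "degenerate": self.degenerate,
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        obj = json.loads(Path(path).read_text())
        return cls(
            center={p: d["center"] for p, d in obj["pathways"].items()},
            scale={p: d["scale"] for p, d in obj["pathways"].items()},
            cap=obj["cap"],
            degenerate=obj.get("degenerate", []),
        )


def fit_scaler(train_scores: pd.DataFrame, cap: float = 10.0) -> ScalerState:
    """Fit a median/IQR scaler per pathway (rows) over training samples (columns).

    Quantiles use linear interpolation.  Zero-IQR pathways get scale 1.0.
    """
    if train_scores.size == 0:
        raise ValueError("empty score matrix")
    if train_scores.shape[1] < 2:
        raise ValueError("need at least 2 training samples to fit a scaler")
    values = train_scores.to_numpy(dtype=float)
    center = np.median(values, axis=1)
    q1 = np.quantile(values, 0.25, axis=1)
    q3 = np.quantile(values, 0.75, axis=1)
    iqr = q3 - q1
    degenerate = [p for p, s in zip(train_scores.index, iqr) if s == 0]
    if degenerate:
        warnings.warn(f"{len(degenerate)} constant pathways: scale set to 1.0", stacklevel=2)
    scale = np.where(iqr == 0, 1.0, iqr)
    return ScalerState(
        center=dict(zip(train_scores.index, center.astype(float))),
        scale=dict(zip(train_scores.index, scale.astype(float))),
        cap=float(cap),
        degenerate=degenerate,
    )


def apply_scaler(scores: pd.DataFrame, state: ScalerState) -> pd.DataFrame:
    """Apply ``(x - center) / scale`` per pathway and clamp to [-cap, +cap]."""
    missing = [p for p in scores.index if p not in state.center]
    extra = [p for p in state.center if p not in set(scores.index)]
    if missing or extra:
        raise ValueError(
            f"pathway mismatch between scores and scaler state: "
            f"unknown to scaler {missing[:5]}, absent from scores {extra[:5]}"
        )
    center = np.array([state.center[p] for p in scores.index])
    scale = np.array([state.scale[p] for p in scores.index])
    z = (scores.to_numpy(dtype=float) - center[:, None]) / scale[:, None]
    z = np.clip(z, -state.cap, state.cap)
    return pd.DataFrame(z, index=scores.index, columns=scores.columns)
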