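"""Blinded cross-validation splits, performance metrics and factor statistics.

Four evaluation scenarios of increasing difficulty:

* ``unblinded``   — response pairs split 8:1:1; every cell and drug may
  appear in all of train/val/test (10 folds);
* ``cell_blind``  — cell lines split 8:1:1, pairs follow their cell (10 folds);
* ``drug_blind``  — same for drugs (10 folds);
* ``strict_blind``— cells and drugs each split into 5 parts; each of the
  25 folds tests on one (cell part x drug part) block, validates on the
  cyclically next block, and trains on the remaining 3x3 blocks (per-axis
  3:1:1).

Metrics are RMSE, Pearson (PCC) and Spearman (SCC) correlations, overall
and per cell/drug; model comparison uses one-tailed Mann-Whitney tests over
fold replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .response import ResponseTable

__all__ = [
    "SplitPlan",
    "Fold",
    "make_splits",
    "compute_metrics",
    "MetricsReport",
    "compare_models",
    "responder_analysis",
    "entity_statistics",
]

Scenario = Literal["unblinded", "cell_blind", "drug_blind", "strict_blind"]


@dataclass
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class SplitPlan:
    scenario: Scenario
    folds: list[Fold]
    seed: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "folds": [
                {"train": f.train.tolist(), "val": f.val.tolist(), "test": f.test.tolist()}
                for f in self.folds
            ],
            "meta": self.meta,
        }


def _deal_round_robin(items: np.ndarray, n_parts: int, rng: np.random.Generator) -> np.ndarray:
    """Assign shuffled items to parts 0..n_parts-1 in rotation (sizes within 1)."""
    order = rng.permutation(len(items))
    part = np.empty(len(items), dtype=np.int64)
    part[order] = np.arange(len(items)) % n_parts
    return part


def make_splits(table: ResponseTable | pd.DataFrame, scenario: Scenario, seed: int) -> SplitPlan:
    """Build the fold plan for one blinding scenario.

    Unblinded folds are approximately stratified: pairs are shuffled within
    each cell and dealt round-robin over the 10 parts, so every cell (and,
    approximately, every drug) is represented in each part.
    """
    df = table.records if isinstance(table, ResponseTable) else table
    df = df.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(df)
    cells = np.sort(df["cell_id"].unique())
    drugs = np.sort(df["drug_id"].unique())

    if scenario == "unblinded":
        part = np.empty(n, dtype=np.int64)
        # deal each cell's pairs round-robin with a random part offset
        for _, idx in df.groupby("cell_id", sort=True).indices.items():
            idx = rng.permutation(idx)
            offset = rng.integers(10)
            part[idx] = (np.arange(len(idx)) + offset) % 10
        folds = []
        for f in range(10):
            test = np.flatnonzero(part == f)
            val = np.flatnonzero(part == (f + 1) % 10)
            train = np.flatnonzero((part != f) & (part != (f + 1) % 10))
            folds.append(Fold(train, val, test))
        return SplitPlan(scenario, folds, seed)

    if scenario in ("cell_blind", "drug_blind"):
        col = "cell_id" if scenario == "cell_blind" else "drug_id"
        entities = cells if scenario == "cell_blind" else drugs
        if len(entities) < 10:
            raise ValueError(f"need at least 10 {col} entities, got {len(entities)}")
        entity_part = dict(zip(entities, _deal_round_robin(entities, 10, rng)))
        part = df[col].map(entity_part).to_numpy(dtype=np.int64)
        folds = []
        for f in range(10):
            test = np.flatnonzero(part == f)
            val = np.flatnonzero(part == (f + 1) % 10)
            train = np.flatnonzero((part != f) & (part != (f + 1) % 10))
            folds.append(Fold(train, val, test))
        return SplitPlan(scenario, folds, seed, meta={"entity_parts": {str(k): int(v) for k, v in entity_part.items()}})

    if scenario == "strict_blind":
        if len(cells) < 10 or len(drugs) < 10:
            raise ValueError("strict_blind needs at least 10 cells and 10 drugs")
        cell_part = dict(zip(cells, _deal_round_robin(cells, 5, rng)))
        drug_part = dict(zip(drugs, _deal_round_robin(drugs, 5, rng)))
        cp = df["cell_id"].map(cell_part).to_numpy(dtype=np.int64)
        dp = df["drug_id"].map(drug_part).to_numpy(dtype=np.int64)
        folds = []
        for i in range(5):
            for j in range(5):
                iv, jv = (i + 1) % 5, (j + 1) % 5
                test = np.flatnonzero((cp == i) & (dp == j))
                val = np.flatnonzero((cp == iv) & (dp == jv))
                train = np.flatnonzero(
                    (cp != i) & (cp != iv) & (dp != j) & (dp != jv)
                )
                folds.append(Fold(train, val, test))
        return SplitPlan(
            scenario,
            folds,
            seed,
            meta={
                "cell_parts": {str(k): int(v) for k, v in cell_part.items()},
                "drug_parts": {str(k): int(v) for k, v in drug_part.items()},
            },
        )

    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class MetricsReport:
    rmse: float
    pcc: float
    scc: float
    n: int
    per_group: pd.DataFrame | None = None


def _safe_corr(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    if np.std(truth) == 0 or np.std(pred) == 0:
        return float("nan"), float("nan")
    pcc = float(stats.pearsonr(pred, truth).statistic)
    scc = float(stats.spearmanr(pred, truth).statistic)
    return pcc, scc


def compute_metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    group_by: np.ndarray | None = None,
    min_group_size: int = 3,
) -> MetricsReport:
    """RMSE / Pearson / Spearman, optionally also within each entity group.

    Groups with fewer than ``min_group_size`` pairs are excluded from the
    per-group frame (rank correlation is meaningless below 3 points).
    Zero-variance truth yields NaN correlations but a valid RMSE.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if len(pred) < 2:
        raise ValueError("need at least 2 pairs")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    pcc, scc = _safe_corr(pred, truth)
    per_group = None
    if group_by is not None:
        rows = []
        frame = pd.DataFrame({"g": group_by, "p": pred, "t": truth})
        for g, sub in frame.groupby("g", sort=True):
            if len(sub) < min_group_size:
                continue
            g_rmse = float(np.sqrt(np.mean((sub["p"] - sub["t"]) ** 2)))
            g_pcc, g_scc = _safe_corr(sub["p"].to_numpy(), sub["t"].to_numpy())
            rows.append({"group": g, "n": len(sub), "rmse": g_rmse, "pcc": g_pcc, "scc": g_scc})
        per_group = pd.DataFrame(rows)
    return MetricsReport(rmse=rmse, pcc=pcc, scc=scc, n=len(pred), per_group=per_group)


def compare_models(
    samples_a, samples_b, better: Literal["lower", "higher"] = "lower"
) -> float:
    """One-tailed Mann-Whitney p-value that model A beats model B.

    ``better='lower'`` tests whether A's replicates are stochastically lower
    (RMSE-style metrics); ``'higher'`` the reverse (correlation metrics).
    Exact for combined n <= 20 without ties, tie-corrected normal
    approximation otherwise.  Two identical constant samples return the 0.5
    convention with a warning.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 replicates per model")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("identical constant samples: p = 0.5 by convention", stacklevel=2)
        return 0.5
    alternative = "less" if better == "lower" else "greater"
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def mannwhitney_one_tailed(a, b, alternative: str = "less") -> float:
    """Exact-where-possible one-tailed Mann-Whitney p-value (thin wrapper)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def responder_analysis(
    responder_preds, non_responder_preds
) -> tuple[float, float]:
    """Effect size and p-value that responders receive lower predictions.

    Effect size = mean(responders) - mean(non-responders); a negative value
    means the model ranks responders as more sensitive, the consistent
    direction.  The p-value is a one-tailed Mann-Whitney (responders lower).
    """
    r = np.asarray(responder_preds, dtype=float)
    nr = np.asarray(non_responder_preds, dtype=float)
    if len(r) == 0 or len(nr) == 0:
        raise ValueError("both responder classes must be non-empty")
    effect = float(r.mean() - nr.mean())
    p = mannwhitney_one_tailed(r, nr, alternative="less")
    return effect, p


def entity_statistics(
    table: ResponseTable | pd.DataFrame, by: Literal["cell", "drug"] = "drug", grid_size: int = 512
) -> pd.DataFrame:
    """Per-entity response distribution statistics.

    Returns count, mean, sample std, Sarle's bimodality coefficient
    (small-sample corrected, from skewness and excess kurtosis) and density
    coverage — the overlap coefficient between the entity's Gaussian KDE and
    the global KDE (Silverman bandwidth, shared grid).  Entities with fewer
    than 4 values get NaN bimodality/coverage.
    """
    df = table.records if isinstance(table, ResponseTable) else table
    col = "cell_id" if by == "cell" else "drug_id"
    values = df["ln_ic50"].to_numpy(dtype=float)
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo or 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    if np.ptp(values) > 0:
        global_kde = stats.gaussian_kde(values, bw_method="silverman")(grid)
    else:
        global_kde = None  # degenerate global distribution: coverage undefined
    step = grid[1] - grid[0]
    rows = []
    for entity, sub in df.groupby(col, sort=True):
        x = sub["ln_ic50"].to_numpy(dtype=float)
        n = len(x)
        mean = float(x.mean())
        std = float(x.std(ddof=1)) if n > 1 else 0.0
        bimodality = coverage = float("nan")
        if n >= 4 and np.ptp(x) > 0 and global_kde is not None:
            g = stats.skew(x, bias=False)
            k = stats.kurtosis(x, bias=False)  # excess kurtosis
            denom = k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
            bimodality = float((g**2 + 1) / denom) if denom != 0 else float("nan")
            kde = stats.gaussian_kde(x, bw_method="silverman")(grid)
            coverage = float(np.minimum(kde, global_kde).sum() * step)
        rows.append(
            {
                col: entity,
                "count": n,
                "mean": mean,
                "std": std,
                "bimodality": bimodality,
                "density_coverage": coverage,
            }
        )
    return pd.DataFrame(rows)
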