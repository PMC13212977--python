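"""A fully synthetic pharmacogenomic "world" for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes:

* a scale-free gene interaction network (Barabasi-Albert, m=3);
* pathways sampled as connected network neighborhoods (so that network
  separation scores are informative), with controllable pairwise overlap;
* latent per-cell pathway activities with a low-rank correlation structure;
* log-normal, TPM-like gene expression driven by pathway activities, with
  cross-platform style batch effects in log space: a monotone dynamic-range
  compression per batch (scale factor gamma) plus independent per-gene
  additive offsets (probe effects);
* drug responses linear in latent activities: ln IC50(c, d) =
  mu_d + sum_p beta_{d,p} activity_{p,c} + noise, with each drug's beta
  sparse (at most 3 causal pathways);
* drugs drawn from a bundled vocabulary of ~640 valid, synthetic
  reagent-like SMILES strings (``data/smiles_vocab.txt``).

Regeneration with the same seed is bitwise reproducible.  What the world
does *not* emulate: count noise models, realistic pathway biology, or any
relation between a drug's chemistry and its causal pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection, write_gmt, write_matrix, write_response_tsv
from .pcn import GeneNetwork

__all__ = [
    "SyntheticWorld",
    "gen_world",
    "gen_drug_smiles",
    "add_score_noise",
    "batch_distortion_ratio",
    "load_smiles_vocab",
]


def load_smiles_vocab() -> list[str]:
    text = resources.files("gcnpath.data").joinpath("smiles_vocab.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


@dataclass
class SyntheticWorld:
    """Ground-truth state of one generated world (see module docstring)."""

    gene_network: GeneNetwork
    pathways: GeneSetCollection
    latent_activity: pd.DataFrame        # pathways x cells, ~N(0,1)
    gene_baseline: np.ndarray            # (n_genes,)
    gene_loadings: dict[str, dict[str, float]]  # gene -> {pathway: loading}
    batch_offsets: np.ndarray            # (n_batches, n_genes), log-space shifts
    batch_scales: np.ndarray             # (n_batches,), log-space compression factors
    gene_noise_sd: float
    drug_table: pd.DataFrame             # drug_id, cid, smiles
    drug_mu: pd.Series                   # per-drug intercept
    drug_beta: pd.DataFrame              # drugs x pathways, sparse rows
    noise_sd: float
    response_link: str
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_baseline_index)

    def __post_init__(self) -> None:
        self.gene_baseline_index = [f"g{i:04d}" for i in range(len(self.gene_baseline))]

    # ---- data products ---------------------------------------------------
    def expression(self, batch: int = 0, noise_seed: int | None = None) -> pd.DataFrame:
        """TPM-like expression (genes x cells) for one batch.

        log-expression = gamma_b * (baseline + sum_p loading * activity)
        + batch offset + N(0, gene_noise_sd); the returned matrix is exp()
        of that, so it is strictly positive and right-skewed like TPM.
        """
        if not 0 <= batch < self.batch_offsets.shape[0]:
            raise ValueError(f"batch {batch} out of range")
        genes = self.gene_baseline_index
        cells = list(self.latent_activity.columns)
        act = self.latent_activity.to_numpy()
        p_pos = {p: i for i, p in enumerate(self.latent_activity.index)}
        log_expr = np.tile(self.gene_baseline[:, None], (1, len(cells)))
        for gi, g in enumerate(genes):
            for p, w in self.gene_loadings.get(g, {}).items():
                log_expr[gi] += w * act[p_pos[p]]
        log_expr *= self.batch_scales[batch]
        log_expr += self.batch_offsets[batch][:, None]
        rng = np.random.default_rng(
            self.seed + 7919 * (batch + 1) if noise_seed is None else noise_seed
        )
        log_expr += rng.normal(0.0, self.gene_noise_sd, size=log_expr.shape)
        return pd.DataFrame(np.exp(log_expr), index=genes, columns=cells)

    def responses(self, pair_fraction: float = 0.5) -> pd.DataFrame:
        """Sample (cell, drug, ln_ic50) records for a fraction of all pairs."""
        cells = list(self.latent_activity.columns)
        drugs = list(self.drug_table["drug_id"])
        act = self.latent_activity.to_numpy()           # (P, C)
        beta = self.drug_beta.to_numpy()                # (D, P)
        signal = beta @ act                             # (D, C)
        if self.response_link == "tanh":
            signal = 2.0 * np.tanh(signal)
        mu = self.drug_mu.to_numpy()[:, None]
        rng = np.random.default_rng(self.seed + 104729)
        y = mu + signal + rng.normal(0.0, self.noise_sd, size=signal.shape)
        dd, cc = np.meshgrid(np.arange(len(drugs)), np.arange(len(cells)), indexing="ij")
        df = pd.DataFrame(
            {
                "cell_id": np.array(cells)[cc.ravel()],
                "drug_id": np.array(drugs)[dd.ravel()],
                "ln_ic50": y.ravel(),
                "source": "SYNTHETIC",
            }
        )
        if pair_fraction < 1.0:
            keep = rng.random(len(df)) < pair_fraction
            df = df[keep].reset_index(drop=True)
        return df

    def causal_pathways(self, drug_id: str) -> list[str]:
        row = self.drug_beta.loc[drug_id]
        return list(row.index[row != 0.0])

    def write_files(self, out_dir: str | Path, pair_fraction: float = 0.5) -> None:
        """Dump every standard-format input file into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gmt(self.pathways, out / "pathways.gmt")
        pd.DataFrame(self.gene_network.graph.edges, columns=["source", "target"]).to_csv(
            out / "network.tsv", sep="\t", index=False, header=False
        )
        for b in range(self.batch_offsets.shape[0]):
            write_matrix(self.expression(batch=b), out / f"expression_batch{b}.tsv")
        self.drug_table.to_csv(out / "drugs.csv", index=False)
        write_response_tsv(self.responses(pair_fraction), out / "responses.tsv")


def gen_drug_smiles(n_drugs: int, seed: int) -> pd.DataFrame:
    """Sample drugs (without replacement) from the bundled SMILES vocabulary."""
    vocab = load_smiles_vocab()
    if n_drugs > len(vocab):
        raise ValueError(f"at most {len(vocab)} drugs available, asked for {n_drugs}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(vocab), size=n_drugs, replace=False)
    return pd.DataFrame(
        {
            "drug_id": [f"DR{i:03d}" for i in range(n_drugs)],
            "cid": [f"SYN{p:04d}" for p in picks],
            "smiles": [vocab[p] for p in picks],
        }
    )


def gen_world(
    n_genes: int = 1200,
    n_pathways: int = 30,
    n_cells: int = 200,
    n_drugs: int = 50,
    n_batches: int = 2,
    overlap_frac: float = 0.25,
    noise_sd: float = 0.3,
    seed: int = 0,
    min_size: int = 12,
    max_size: int = 28,
    loading_range: tuple[float, float] = (0.5, 1.5),
    batch_sd: float = 0.4,
    batch_scale_range: tuple[float, float] = (0.55, 0.75),
    gene_noise_sd: float = 0.1,
    n_factors: int = 5,
    max_causal: int = 3,
    sensitizing_frac: float = 0.8,
    scrambled_pathways: bool = False,
    response_link: str = "linear",
) -> SyntheticWorld:
    """Generate a complete synthetic world (see module docstring).

    ``overlap_frac`` is the probability that a pathway is seeded inside an
    already-sampled pathway (creating gene overlap); ``scrambled_pathways``
    samples members uniformly instead of as network neighborhoods (the null
    case for topology-perturbation experiments).
    """
    if n_pathways * min_size > n_genes * (1 + overlap_frac):
        raise ValueError("infeasible sizes: too many/large pathways for the gene pool")
    if response_link not in ("linear", "tanh"):
        raise ValueError("response_link must be 'linear' or 'tanh'")
    rng = np.random.default_rng(seed)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    ba = nx.barabasi_albert_graph(n_genes, 3, seed=int(rng.integers(2**31)))
    network = GeneNetwork((genes[a], genes[b]) for a, b in ba.edges)

    # pathways as connected neighborhoods (BFS from a seed gene)
    sets: dict[str, frozenset[str]] = {}
    used: set[int] = set()
    for pi in range(n_pathways):
        size = int(rng.integers(min_size, max_size + 1))
        if scrambled_pathways:
            members = rng.choice(n_genes, size=size, replace=False).tolist()
        else:
            if used and rng.random() < overlap_frac:
                seed_gene = int(rng.choice(sorted(used)))
            else:
                fresh = sorted(set(range(n_genes)) - used)
                seed_gene = int(rng.choice(fresh))
            members = [seed_gene]
            frontier = [seed_gene]
            while len(members) < size and frontier:
                nbrs = sorted(
                    {nb for node in frontier for nb in ba.neighbors(node)} - set(members)
                )
                if not nbrs:
                    break
                take = min(size - len(members), len(nbrs))
                picked = rng.choice(nbrs, size=take, replace=False).tolist()
                members.extend(int(x) for x in picked)
                frontier = picked
        used.update(members)
        sets[f"PW{pi:03d}"] = frozenset(genes[m] for m in members)
    pathways = GeneSetCollection(sets, provenance=f"synthetic neighborhoods seed={seed}")

    # latent activities: low-rank factor structure, approx N(0,1) marginals
    factors = rng.normal(size=(n_factors, n_cells))
    load = rng.normal(scale=1.0 / np.sqrt(n_factors), size=(n_pathways, n_factors))
    unique = rng.normal(scale=0.6, size=(n_pathways, n_cells))
    act = load @ factors + unique
    act = (act - act.mean(axis=1, keepdims=True)) / act.std(axis=1, keepdims=True)
    cells = [f"CL{i:03d}" for i in range(n_cells)]
    latent = pd.DataFrame(act, index=list(sets), columns=cells)

    gene_baseline = rng.normal(3.0, 1.0, size=n_genes)
    loadings: dict[str, dict[str, float]] = {}
    for pname, members in sets.items():
        for g in sorted(members):
            loadings.setdefault(g, {})[pname] = float(rng.uniform(*loading_range))
    batch_offsets = np.zeros((n_batches, n_genes))
    batch_scales = np.ones(n_batches)
    if n_batches > 1:
        batch_offsets[1:] = rng.normal(0.0, batch_sd, size=(n_batches - 1, n_genes))
        batch_scales[1:] = rng.uniform(*batch_scale_range, size=n_batches - 1)

    drug_table = gen_drug_smiles(n_drugs, seed=int(rng.integers(2**31)))
    mu = pd.Series(rng.normal(2.0, 1.0, size=n_drugs), index=drug_table["drug_id"])
    beta = np.zeros((n_drugs, n_pathways))
    # causal effects are mostly sensitizing (beta < 0): cells with high
    # activity of a drug's target pathway respond at lower concentrations
    # (oncogene addiction); the remainder model resistance pathways
    for di in range(n_drugs):
        k = int(rng.integers(1, max_causal + 1))
        targets = rng.choice(n_pathways, size=k, replace=False)
        signs = np.where(rng.random(k) < sensitizing_frac, -1.0, 1.0)
        beta[di, targets] = signs * rng.uniform(0.8, 1.6, size=k)
    beta_df = pd.DataFrame(beta, index=drug_table["drug_id"], columns=list(sets))

    return SyntheticWorld(
        gene_network=network,
        pathways=pathways,
        latent_activity=latent,
        gene_baseline=gene_baseline,
        gene_loadings=loadings,
        batch_offsets=batch_offsets,
        batch_scales=batch_scales,
        gene_noise_sd=gene_noise_sd,
        drug_table=drug_table,
        drug_mu=mu,
        drug_beta=beta_df,
        noise_sd=noise_sd,
        response_link=response_link,
        seed=seed,
    )


def add_score_noise(scores: pd.DataFrame, sd: float, seed: int) -> pd.DataFrame:
    """Add elementwise Gaussian N(0, sd^2) noise to a score matrix."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return scores.copy()
    rng = np.random.default_rng(seed)
    return scores + rng.normal(0.0, sd, size=scores.shape)


def batch_distortion_ratio(features_b1: pd.DataFrame, features_b2: pd.DataFrame) -> float:
    """Scale-free measure of batch distortion for one feature representation.

    Both frames are features x samples for the *same* samples measured in two
    batches.  Returns the mean within-sample cross-batch Euclidean distance
    divided by the mean between-sample distance within batch 1.  Values near
    0 mean the representation is batch-insensitive; values near or above 1
    mean batch separation dominates biological separation.
    """
    if list(features_b1.columns) != list(features_b2.columns):
        raise ValueError("both batches must cover the same samples in order")
    a = features_b1.to_numpy(dtype=float).T  # samples x features
    b = features_b2.to_numpy(dtype=float).T
    cross = np.linalg.norm(a - b, axis=1).mean()
    n = a.shape[0]
    idx = np.triu_indices(n, k=1)
    within = np.linalg.norm(a[idx[0]] - a[idx[1]], axis=1).mean()
    return float(cross / within)
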