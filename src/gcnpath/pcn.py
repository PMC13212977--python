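"""Pathway crosstalk network (PCN) construction.

A PCN is a directed graph over pathways with three edge relations:

* ``ppi``  — derived from a protein-protein interaction network via the
  network separation score s_AB = <d_AB> - (<d_AA> + <d_BB>)/2, where the
  d terms are mean shortest-path distances between/within the two gene sets;
* ``grn``  — same construction on a gene regulatory network;
* ``corr`` — Pearson correlation of pathway activity scores across samples.

Each pathway keeps directed edges to its K closest neighbors per relation
(lowest separation, or highest correlation).  When fewer than K separation
scores exist (disconnected gene sets), the shortfall is filled by the highest
gene overlap (Jaccard) ratios.  Neighbor selection is not symmetric, so the
graph is genuinely directed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection, write_json, read_json

__all__ = [
    "GeneNetwork",
    "PCNGraph",
    "shortest_distances",
    "separation_score",
    "separation_table",
    "overlap_ratio",
    "overlap_table",
    "pathway_correlations",
    "build_knn_relation",
    "assemble_pcn",
    "perturb_pcn",
    "build_pcn",
]

RELATIONS = ("ppi", "grn", "corr")
DistanceConvention = Literal["nearest", "all_pairs"]


class GeneNetwork:
    """Undirected gene/protein interaction network (hop distances only)."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(str(a), str(b))
        self.graph = g

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, min_confidence: float | None = None) -> "GeneNetwork":
        if min_confidence is not None and "confidence" in df.columns:
            df = df[df["confidence"] >= min_confidence]
        return cls(zip(df["source"], df["target"]))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def shortest_distances(net: GeneNetwork, genes: Iterable[str]) -> dict[str, dict[str, float]]:
    """BFS hop distances from each surviving gene to every reachable node.

    Genes absent from the network are dropped with a warning; unreachable
    targets are reported as ``inf`` by callers indexing with ``.get``.
    """
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in net.graph]
    absent = set(genes) - set(present)
    if absent:
        warnings.warn(f"{len(absent)} genes absent from network dropped", stacklevel=2)
    if not present:
        raise ValueError("no query gene is present in the network")
    return {g: nx.single_source_shortest_path_length(net.graph, g) for g in present}


def _mean_or_inf(values: list[float]) -> float:
    return float(np.mean(values)) if values else np.inf


def _within_distance(dist: Mapping[str, Mapping[str, int]], members: list[str], convention: str) -> float:
    """Mean within-set distance <d_XX>; singleton sets contribute 0."""
    if len(members) < 2:
        return 0.0
    if convention == "nearest":
        per_gene = []
        for g in members:
            dmap = dist[g]
            best = min((dmap.get(h, np.inf) for h in members if h != g), default=np.inf)
            per_gene.append(best)
        return _mean_or_inf(per_gene)
    # all-pairs mean over unordered pairs
    vals = []
    for i, g in enumerate(members):
        dmap = dist[g]
        for h in members[i + 1:]:
            vals.append(dmap.get(h, np.inf))
    return _mean_or_inf(vals)


def _between_distance(
    dist: Mapping[str, Mapping[str, int]], a: list[str], b: list[str], convention: str
) -> float:
    if convention == "nearest":
        per_gene = []
        b_set, a_set = b, a
        for g in a:
            per_gene.append(min((dist[g].get(h, np.inf) for h in b_set), default=np.inf))
        for g in b:
            per_gene.append(min((dist[g].get(h, np.inf) for h in a_set), default=np.inf))
        return _mean_or_inf(per_gene)
    vals = [dist[g].get(h, np.inf) for g in a for h in b]
    return _mean_or_inf(vals)


def separation_score(
    net: GeneNetwork,
    set_a: Iterable[str],
    set_b: Iterable[str],
    convention: DistanceConvention = "nearest",
    _dist: Mapping[str, Mapping[str, int]] | None = None,
) -> float | None:
    """Network separation s_AB of two gene sets, or ``None`` when undefined.

    Under the ``nearest`` convention each gene contributes its distance to
    the closest gene of the other set (cross term) or the closest *other*
    member of its own set (within term); ``all_pairs`` averages over all
    gene pairs.  Any infinite required distance makes the score undefined
    (disconnected gene sets carry no separation information).
    """
    a = sorted(set(set_a) & net.nodes)
    b = sorted(set(set_b) & net.nodes)
    if not a or not b:
        return None
    if _dist is None:
        _dist = shortest_distances(net, a + b)
    d_ab = _between_distance(_dist, a, b, convention)
    d_aa = _within_distance(_dist, a, convention)
    d_bb = _within_distance(_dist, b, convention)
    if not np.isfinite(d_ab) or not np.isfinite(d_aa) or not np.isfinite(d_bb):
        return None
    return float(d_ab - (d_aa + d_bb) / 2.0)


def separation_table(
    net: GeneNetwork,
    sets: GeneSetCollection,
    convention: DistanceConvention = "nearest",
) -> pd.DataFrame:
    """All pairwise separation scores (NaN where undefined)."""
    ids = sets.pathway_ids
    members = {p: sorted(sets.sets[p] & net.nodes) for p in ids}
    all_genes = sorted({g for m in members.values() for g in m})
    if not all_genes:
        raise ValueError("no pathway gene is present in the network")
    dist = {g: nx.single_source_shortest_path_length(net.graph, g) for g in all_genes}
    n = len(ids)
    out = np.full((n, n), np.nan)
    within = {}
    for i, p in enumerate(ids):
        if members[p]:
            within[p] = _within_distance(dist, members[p], convention)
    for i, p in enumerate(ids):
        a = members[p]
        if not a or not np.isfinite(within[p]):
            continue
        for j in range(i + 1, n):
            q = ids[j]
            bm = members[q]
            if not bm or not np.isfinite(within[q]):
                continue
            d_ab = _between_distance(dist, a, bm, convention)
            if np.isfinite(d_ab):
                out[i, j] = out[j, i] = d_ab - (within[p] + within[q]) / 2.0
        out[i, i] = -within[p]  # s_AA = 0 - d_AA
    return pd.DataFrame(out, index=ids, columns=ids)


def overlap_ratio(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard gene overlap ratio |A n B| / |A u B|."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both gene sets are empty")
    return len(a & b) / len(a | b)


def overlap_table(sets: GeneSetCollection) -> pd.DataFrame:
    ids = sets.pathway_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i, p in enumerate(ids):
        for j in range(i, n):
            out[i, j] = out[j, i] = overlap_ratio(sets.sets[p], sets.sets[ids[j]])
    return pd.DataFrame(out, index=ids, columns=ids)


def pathway_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of pathway scores across samples.

    Zero-variance pathways get NaN correlations (with a warning) so they are
    excluded from neighbor ranking rather than spuriously tied.
    """
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 samples for pathway correlations")
    values = scores.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance pathways: correlations undefined", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    return pd.DataFrame(corr, index=scores.index, columns=scores.index)


def build_knn_relation(
    primary: pd.DataFrame,
    k: int,
    higher_is_closer: bool,
    fallback: pd.DataFrame | None = None,
) -> list[tuple[str, str]]:
    """Directed K-nearest-neighbor edges from a square affinity table.

    For each source pathway, rank defined (non-NaN) off-diagonal scores —
    ascending for separation scores, descending for correlations — and keep
    the top ``k``.  A shortfall is filled from ``fallback`` (highest values
    first), skipping pathways already selected.  Ties break lexicographically
    by pathway id so builds are deterministic.
    """
    ids = list(primary.index)
    if list(primary.columns) != ids:
        raise ValueError("primary table must be square with identical index/columns")
    if len(ids) - 1 < k:
        warnings.warn(f"only {len(ids) - 1} candidate pathways for K={k}: taking all", stacklevel=2)
    edges: list[tuple[str, str]] = []
    for src in ids:
        row = primary.loc[src]
        cands = [(row[t], t) for t in ids if t != src and np.isfinite(row[t])]
        cands.sort(key=lambda vt: (-vt[0] if higher_is_closer else vt[0], vt[1]))
        chosen = [t for _, t in cands[:k]]
        if len(chosen) < k and fallback is not None:
            frow = fallback.loc[src]
            pool = [
                (frow[t], t)
                for t in ids
                if t != src and t not in chosen and np.isfinite(frow[t])
            ]
            pool.sort(key=lambda vt: (-vt[0], vt[1]))  # fallback: highest overlap first
            chosen.extend(t for _, t in pool[: k - len(chosen)])
        edges.extend((src, t) for t in chosen)
    return edges


@dataclass
class PCNGraph:
    """Directed multi-relation pathway graph with a fixed node order."""

    pathway_ids: list[str]
    edges: list[tuple[str, str, str]]  # (source, target, relation)
    k: int = 5

    def __post_init__(self) -> None:
        known = set(self.pathway_ids)
        for s, t, r in self.edges:
            if s not in known or t not in known:
                raise ValueError(f"edge references unknown pathway: {(s, t, r)}")
            if r not in RELATIONS:
                raise ValueError(f"unknown relation {r!r}")
            if s == t:
                raise ValueError(f"self-edge not allowed: {(s, t, r)}")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    def edges_of(self, relation: str) -> list[tuple[str, str]]:
        return [(s, t) for s, t, r in self.edges if r == relation]

    def edge_index(self, relation: str) -> np.ndarray:
        """(2, E) integer array in node order; edges point source -> target."""
        pos = {p: i for i, p in enumerate(self.pathway_ids)}
        pairs = self.edges_of(relation)
        if not pairs:
            return np.zeros((2, 0), dtype=np.int64)
        return np.array([[pos[s] for s, _ in pairs], [pos[t] for _, t in pairs]], dtype=np.int64)

    def out_degrees(self, relation: str) -> dict[str, int]:
        deg = {p: 0 for p in self.pathway_ids}
        for s, _ in self.edges_of(relation):
            deg[s] += 1
        return deg

    def to_files(self, edges_tsv: str | Path, header_json: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "relation"]).to_csv(
            edges_tsv, sep="\t", index=False
        )
        write_json({"pathway_ids": self.pathway_ids, "k": self.k}, header_json)

    @classmethod
    def from_files(cls, edges_tsv: str | Path, header_json: str | Path) -> "PCNGraph":
        hdr = read_json(header_json)
        df = pd.read_csv(edges_tsv, sep="\t", dtype=str)
        edges = list(df.itertuples(index=False, name=None))
        return cls(pathway_ids=list(hdr["pathway_ids"]), edges=edges, k=int(hdr["k"]))


def assemble_pcn(
    ppi_edges: list[tuple[str, str]],
    grn_edges: list[tuple[str, str]],
    corr_edges: list[tuple[str, str]],
    pathway_order: list[str],
    k: int = 5,
) -> PCNGraph:
    """Combine the three directed relations into one typed-edge graph."""
    tagged: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    dupes = 0
    for rel, edge_list in zip(RELATIONS, (ppi_edges, grn_edges, corr_edges)):
        if not edge_list:
            warnings.warn(f"relation {rel!r} has no edges", stacklevel=2)
        for s, t in edge_list:
            key = (s, t, rel)
            if key in seen:
                dupes += 1
                continue
            seen.add(key)
            tagged.append(key)
    if dupes:
        warnings.warn(f"removed {dupes} duplicate typed edges", stacklevel=2)
    return PCNGraph(pathway_ids=list(pathway_order), edges=tagged, k=k)


def perturb_pcn(pcn: PCNGraph, seed: int, n_swaps_per_edge: int = 10) -> PCNGraph:
    """Degree-preserving random rewiring of each relation (double-edge swaps).

    Repeatedly picks two edges (a->b, c->d) within a relation and swaps their
    targets to (a->d, c->b), rejecting swaps that would introduce self-loops
    or duplicate edges.  Out- and in-degree multisets per relation are exactly
    preserved.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    new_edges: list[tuple[str, str, str]] = []
    for rel in RELATIONS:
        pairs = pcn.edges_of(rel)
        if len(pairs) < 2:
            new_edges.extend((s, t, rel) for s, t in pairs)
            continue
        pairs = [list(p) for p in pairs]
        existing = {tuple(p) for p in pairs}
        n_target = n_swaps_per_edge * len(pairs)
        attempts, successes = 0, 0
        max_attempts = 20 * n_target
        while successes < n_target and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, len(pairs), size=2)
            if i == j:
                continue
            a, b = pairs[i]
            c, d = pairs[j]
            if a == d or c == b:
                continue
            if (a, d) in existing or (c, b) in existing:
                continue
            existing.discard((a, b))
            existing.discard((c, d))
            pairs[i][1], pairs[j][1] = d, b
            existing.add((a, d))
            existing.add((c, b))
            successes += 1
        if successes < n_target:
            warnings.warn(
                f"relation {rel!r}: only {successes}/{n_target} swaps achieved", stacklevel=2
            )
        new_edges.extend((s, t, rel) for s, t in pairs)
    return PCNGraph(pathway_ids=list(pcn.pathway_ids), edges=new_edges, k=pcn.k)


def build_pcn(
    ppi_net: GeneNetwork,
    grn_net: GeneNetwork,
    scores: pd.DataFrame,
    sets: GeneSetCollection,
    k: int = 5,
    convention: DistanceConvention = "nearest",
) -> PCNGraph:
    """End-to-end PCN construction from raw networks, scores and gene sets."""
    order = sets.pathway_ids
    if list(scores.index) != order:
        scores = scores.loc[order]
    ov = overlap_table(sets)
    ppi = build_knn_relation(
        separation_table(ppi_net, sets, convention), k, higher_is_closer=False, fallback=ov
    )
    grn = build_knn_relation(
        separation_table(grn_net, sets, convention), k, higher_is_closer=False, fallback=ov
    )
    corr = build_knn_relation(pathway_correlations(scores), k, higher_is_closer=True)
    return assemble_pcn(ppi, grn, corr, order, k=k)
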