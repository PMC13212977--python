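"""The drug response regression network and Grad-CAM pathway attribution.

Architecture
------------
* **Cell encoder** — three relation-typed graph convolutions over the PCN
  (relations ppi/grn/corr), densely wired: layer *i* consumes the
  concatenation of the raw pathway score and all previous layer outputs.
  The three layer outputs are concatenated per pathway (8+8+8 = 24 channels
  by default), flattened across pathways, and projected to the cell
  embedding.  Flattening (rather than pooling) preserves pathway identity,
  which is also what makes Grad-CAM attribution per pathway meaningful.
* **Drug encoder** — three multi-head graph attention layers over the
  atom-bond graph with the same dense wiring, global max pooling over
  atoms, then a projection to the drug embedding.
* **Prediction head** — the two embeddings are concatenated and passed
  through two fully connected layers to a scalar ln(IC50) estimate.

Grad-CAM on the first cell layer: with activations A (pathways x channels)
and channel weights alpha_k = mean_p dY/dA[p,k], pathway importance is
ReLU(sum_k alpha_k A[p,k]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .drugs import DrugGraph
from .nn.autodiff import Tensor, concat, gather_rows, segment_max
from .nn.layers import GATLayer, Linear, Module, RGCNLayer
from .pcn import PCNGraph, RELATIONS

__all__ = ["ModelConfig", "GCNPathModel", "AttributionResult", "batch_drug_graphs"]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The standard configuration is ``cell_hidden=[8,8,8]`` (per-pathway
    output 24), ``drug_hidden=[128,128,128]`` with 4 attention heads, and
    256-dimensional cell/drug embeddings feeding a 512 -> head -> 1
    prediction head.  All widths are configurable; the drug per-atom output
    is ``sum(drug_hidden)`` under plain concatenation.
    """

    n_pathways: int = 292
    n_relations: int = 3
    cell_hidden: list[int] = field(default_factory=lambda: [8, 8, 8])
    drug_hidden: list[int] = field(default_factory=lambda: [128, 128, 128])
    gat_heads: int = 4
    cell_embed: int = 256
    drug_embed: int = 256
    head_hidden: list[int] = field(default_factory=lambda: [128])
    atom_feat_dim: int = 85
    bond_feat_dim: int = 10
    dropout: float = 0.2
    lr: float = 1e-4
    batch_size: int = 256
    seed: int = 0

    @property
    def cell_out_dim(self) -> int:
        return sum(self.cell_hidden)

    @property
    def drug_out_dim(self) -> int:
        return sum(self.drug_hidden)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class AttributionResult:
    """Grad-CAM pathway importance for one (cell, drug) pair."""

    pathway_ids: list[str]
    importance: np.ndarray
    top_k: list[str]

    def __post_init__(self) -> None:
        if len(self.importance) != len(self.pathway_ids):
            raise ValueError("one importance value per pathway required")
        if (self.importance < 0).any():
            raise ValueError("importance must be non-negative (post-ReLU)")


def batch_drug_graphs(graphs: list[DrugGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint-union batching of drug graphs.

    Returns (atom_features, bond_index, bond_features, graph_ids) with node
    indices offset per graph.
    """
    feats, eis, eas, gids = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        feats.append(g.atom_features)
        eis.append(g.bond_index + offset)
        eas.append(g.bond_features)
        gids.append(np.full(g.n_atoms, gi, dtype=np.int64))
        offset += g.n_atoms
    return (
        np.concatenate(feats, axis=0),
        np.concatenate(eis, axis=1),
        np.concatenate(eas, axis=0),
        np.concatenate(gids),
    )


class GCNPathModel(Module):
    """End-to-end ln(IC50) regressor over (PCN cell graph, atom-bond drug graph)."""

    def __init__(self, config: ModelConfig, pcn: PCNGraph):
        if pcn.n_pathways != config.n_pathways:
            raise ValueError(
                f"config says {config.n_pathways} pathways, PCN has {pcn.n_pathways}"
            )
        self.config = config
        self.pcn = pcn
        rng = np.random.default_rng(config.seed)

        self.adjacencies = [
            RGCNLayer.normalized_adjacency(pcn.edge_index(rel), pcn.n_pathways)
            for rel in RELATIONS[: config.n_relations]
        ]

        # cell encoder: dense wiring — layer i input = 1 + sum(hidden[:i])
        self.cell_layers = []
        in_dim = 1
        for width in config.cell_hidden:
            self.cell_layers.append(RGCNLayer(in_dim, width, config.n_relations, rng))
            in_dim += width
        self.cell_fc = Linear(config.n_pathways * config.cell_out_dim, config.cell_embed, rng)

        # drug encoder
        self.drug_layers = []
        in_dim = config.atom_feat_dim
        for width in config.drug_hidden:
            self.drug_layers.append(
                GATLayer(in_dim, width, config.gat_heads, config.bond_feat_dim, rng)
            )
            in_dim += width
        self.drug_fc = Linear(config.drug_out_dim, config.drug_embed, rng)

        # prediction head: two FC layers from the fused embedding to a scalar
        head_dims = [config.cell_embed + config.drug_embed, *config.head_hidden, 1]
        self.head_layers = [
            Linear(a, b, rng) for a, b in zip(head_dims[:-1], head_dims[1:])
        ]
        self._train_mode = False
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    # ---- modes -----------------------------------------------------------
    def train(self) -> "GCNPathModel":
        self._train_mode = True
        return self

    def eval(self) -> "GCNPathModel":
        self._train_mode = False
        return self

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self._train_mode or p <= 0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    # ---- forward passes --------------------------------------------------
    def cell_forward(self, scores: np.ndarray, keep_activations: bool = False) -> Tensor:
        """Encode scaled pathway scores (n_pathways,) or (B, n_pathways).

        With ``keep_activations`` the post-activation output of the first
        graph layer is stored on ``self._first_cell_activation`` for Grad-CAM.
        """
        arr = np.asarray(scores, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.config.n_pathways:
            raise ValueError(
                f"expected {self.config.n_pathways} pathway scores, got {arr.shape[1]}"
            )
        x = Tensor(arr[:, :, None])  # (B, P, 1)
        hidden: list[Tensor] = []
        for i, layer in enumerate(self.cell_layers):
            inp = x if not hidden else concat([x, *hidden], axis=-1)
            h = layer(inp, self.adjacencies).elu()
            if i == 0 and keep_activations:
                self._first_cell_activation = h
            hidden.append(h)
        per_pathway = concat(hidden, axis=-1)  # (B, P, sum(cell_hidden))
        flat = per_pathway.reshape(arr.shape[0], -1)
        return self.cell_fc(flat).relu()

    def drug_forward(self, graphs: list[DrugGraph] | DrugGraph) -> Tensor:
        """Encode one or more drug graphs into (B, drug_embed) embeddings."""
        if isinstance(graphs, DrugGraph):
            graphs = [graphs]
        feats, ei, ea, gids = batch_drug_graphs(graphs)
        x = Tensor(feats)
        hidden: list[Tensor] = []
        for layer in self.drug_layers:
            inp = x if not hidden else concat([x, *hidden], axis=-1)
            hidden.append(layer(inp, ei, ea).elu())
        per_atom = concat(hidden, axis=-1)
        pooled = segment_max(per_atom, gids, len(graphs))
        return self.drug_fc(pooled).relu()

    def predict_from_embeddings(self, cell_emb: Tensor, drug_emb: Tensor) -> Tensor:
        if cell_emb.shape[-1] != self.config.cell_embed or drug_emb.shape[-1] != self.config.drug_embed:
            raise ValueError("embedding dimensions do not match config")
        z = concat([cell_emb, drug_emb], axis=-1)
        for i, layer in enumerate(self.head_layers):
            z = self._dropout(z)
            z = layer(z)
            if i < len(self.head_layers) - 1:
                z = z.relu()
        return z

    def forward_pairs(
        self,
        scores: np.ndarray,
        cell_idx: np.ndarray,
        graphs: list[DrugGraph],
        drug_idx: np.ndarray,
        keep_activations: bool = False,
    ) -> Tensor:
        """Predict ln(IC50) for pairs; cells/drugs are deduplicated upstream.

        ``scores`` is (n_unique_cells, n_pathways); ``cell_idx``/``drug_idx``
        map each pair to a row of scores / an entry of ``graphs``.
        """
        cell_emb = self.cell_forward(scores, keep_activations=keep_activations)
        drug_emb = self.drug_forward(graphs)
        return self.predict_from_embeddings(
            gather_rows(cell_emb, cell_idx), gather_rows(drug_emb, drug_idx)
        )

    def predict(self, scores: np.ndarray, cell_idx, graphs, drug_idx) -> np.ndarray:
        """Eval-mode prediction returning a plain (n_pairs,) array."""
        was_training = self._train_mode
        self.eval()
        out = self.forward_pairs(
            scores, np.asarray(cell_idx), graphs, np.asarray(drug_idx)
        ).data[:, 0]
        self._train_mode = was_training
        return out

    # ---- attribution -----------------------------------------------------
    def grad_cam(
        self,
        cell_scores: np.ndarray,
        drug_graph: DrugGraph,
        top_k: int = 5,
        target: str = "sensitivity",
        weighting: str = "elementwise",
    ) -> AttributionResult:
        """Grad-CAM pathway importance for one (cell, drug) pair.

        ``target`` picks the attribution direction: ``"sensitivity"``
        backpropagates from the negative predicted ln(IC50), highlighting
        pathways that drive the prediction toward drug response — the
        relevant direction when explaining a sensitive pair; ``"response"``
        uses the raw prediction and highlights resistance-driving pathways.

        ``weighting`` selects how first-layer gradients are combined:

        * ``"elementwise"`` (default) — importance_p =
          ReLU(sum_k dYt/dA[p,k] * A[p,k]), the gradient x activation form.
          Because this cell encoder *flattens* pathway embeddings through
          pathway-specific head weights (no global pooling), per-pathway
          gradients carry the credit signal directly, and this is the
          faithful Grad-CAM analog for such a head.
        * ``"channel_mean"`` — classic Grad-CAM: alpha_k =
          mean_p dYt/dA[p,k]; importance_p = ReLU(sum_k alpha_k A[p,k]).
          Canonical for pooling heads with position-shared weights; with a
          flatten head, averaging gradients over pathways discards the
          per-pathway credit and the residual direction is
          initialization-dependent.
        """
        if target not in ("sensitivity", "response"):
            raise ValueError("target must be 'sensitivity' or 'response'")
        if weighting not in ("elementwise", "channel_mean"):
            raise ValueError("weighting must be 'elementwise' or 'channel_mean'")
        self.eval()
        self.zero_grad()
        pred = self.forward_pairs(
            np.asarray(cell_scores, dtype=np.float64)[None, :],
            np.array([0]),
            [drug_graph],
            np.array([0]),
            keep_activations=True,
        )
        act = self._first_cell_activation  # (1, P, C)
        (pred * (-1.0 if target == "sensitivity" else 1.0)).backward()
        grads = act.grad[0]                # (P, C)
        activ = act.data[0]
        if weighting == "channel_mean":
            alpha = grads.mean(axis=0)     # channel weights
            importance = np.maximum(activ @ alpha, 0.0)
        else:
            importance = np.maximum((grads * activ).sum(axis=1), 0.0)
        order = np.argsort(-importance, kind="stable")
        ids = self.pcn.pathway_ids
        return AttributionResult(
            pathway_ids=list(ids),
            importance=importance,
            top_k=[ids[i] for i in order[:top_k]],
        )

    # ---- serialization ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights + config + PCN to a single .npz checkpoint."""
        arrays = {f"param/{k}": v for k, v in self.state_dict().items()}
        header = {
            "config": self.config.to_dict(),
            "pathway_ids": self.pcn.pathway_ids,
            "k": self.pcn.k,
            "edges": self.pcn.edges,
        }
        arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GCNPathModel":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(bytes(data["header"].tobytes()).decode())
            state = {
                k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
            }
        pcn = PCNGraph(
            pathway_ids=list(header["pathway_ids"]),
            edges=[tuple(e) for e in header["edges"]],
            k=int(header["k"]),
        )
        model = cls(ModelConfig.from_dict(header["config"]), pcn)
        model.load_state_dict(state)
        return model
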