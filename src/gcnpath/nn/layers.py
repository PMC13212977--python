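"""Neural network layers built on the autodiff core.

Includes dense (fully connected) layers, the relation-typed graph
convolution used by the cell encoder, and the multi-head graph attention
convolution used by the drug encoder.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, gather_rows, matmul_const_left, scatter_sum

__all__ = ["Parameter", "Module", "Linear", "RGCNLayer", "GATLayer", "segment_softmax"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: collects Parameters from attributes and sub-modules."""

    def parameters(self) -> dict[str, Parameter]:
        params: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        params[f"{name}.{i}"] = item
                    elif isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameters in state: {sorted(missing)[:5]}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class RGCNLayer(Module):
    """Relational graph convolution with one weight matrix per relation.

    h_i' = W_self x_i + sum_r sum_{j in N_r(i)} x_j W_r / |N_r(i)| + b

    The normalized adjacency per relation is precomputed as a dense (P, P)
    matrix (pathway graphs are small); edges point source -> target and
    messages are mean-aggregated at the target.  Nodes without incoming
    edges in a relation receive nothing from it (the self term plays the
    role of an implicit self-loop relation, so isolated nodes still update).
    """

    def __init__(self, n_in: int, n_out: int, n_relations: int, rng: np.random.Generator):
        self.w_self = Parameter(_glorot(rng, n_in, n_out))
        self.w_rel = [Parameter(_glorot(rng, n_in, n_out)) for _ in range(n_relations)]
        self.bias = Parameter(np.zeros(n_out))
        self.n_relations = n_relations

    @staticmethod
    def normalized_adjacency(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
        """Dense A_hat with A_hat[t, s] = 1 / in_degree(t) for each edge s->t."""
        a = np.zeros((n_nodes, n_nodes))
        if edge_index.size:
            src, tgt = edge_index
            np.add.at(a, (tgt, src), 1.0)
            deg = a.sum(axis=1, keepdims=True)
            deg[deg == 0] = 1.0
            a /= deg
        return a

    def __call__(self, x: Tensor, adjacencies: list[np.ndarray]) -> Tensor:
        if len(adjacencies) != self.n_relations:
            raise ValueError("one adjacency per relation required")
        out = x @ self.w_self
        for a_hat, w in zip(adjacencies, self.w_rel):
            out = out + matmul_const_left(a_hat, x) @ w
        return out + self.bias


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of ``scores`` (E, 1) within segments (numerically stabilized).

    The per-segment maximum is treated as a constant shift, which leaves the
    softmax value and gradient unchanged.
    """
    shift = np.full(n_segments, -np.inf)
    np.maximum.at(shift, segment_ids, scores.data[:, 0])
    shift[~np.isfinite(shift)] = 0.0
    z = (scores - shift[segment_ids][:, None]).exp()
    denom = scatter_sum(z, segment_ids, n_segments)
    return z / gather_rows(denom, segment_ids)


class GATLayer(Module):
    """Multi-head graph attention convolution with edge features.

    Per head: node projections h = x W; the attention logit of edge j -> i is
    LeakyReLU(a_src . h_j + a_dst . h_i + a_edge . (e_ij W_e)), softmaxed over
    the incoming edges of i; messages are the attention-weighted sum of
    source projections.  Head outputs are concatenated and projected back to
    ``n_out`` so stacked layers keep the stated hidden widths.

    Self-loops (with zero edge features) are appended internally so every
    atom attends at least to itself.
    """

    def __init__(
        self, n_in: int, n_out: int, n_heads: int, edge_dim: int, rng: np.random.Generator
    ):
        self.n_heads = n_heads
        self.n_out = n_out
        self.w = [Parameter(_glorot(rng, n_in, n_out)) for _ in range(n_heads)]
        self.w_edge = [Parameter(_glorot(rng, edge_dim, n_out)) for _ in range(n_heads)]
        self.a_src = [Parameter(_glorot(rng, n_out, 1)) for _ in range(n_heads)]
        self.a_dst = [Parameter(_glorot(rng, n_out, 1)) for _ in range(n_heads)]
        self.a_edge = [Parameter(_glorot(rng, n_out, 1)) for _ in range(n_heads)]
        self.proj = Parameter(_glorot(rng, n_heads * n_out, n_out))
        self.bias = Parameter(np.zeros(n_out))

    @staticmethod
    def with_self_loops(
        edge_index: np.ndarray, edge_attr: np.ndarray, n_nodes: int
    ) -> tuple[np.ndarray, np.ndarray]:
        loops = np.arange(n_nodes, dtype=np.int64)
        ei = np.concatenate([edge_index, np.stack([loops, loops])], axis=1)
        ea = np.concatenate([edge_attr, np.zeros((n_nodes, edge_attr.shape[1]))], axis=0)
        return ei, ea

    def __call__(self, x: Tensor, edge_index: np.ndarray, edge_attr: np.ndarray) -> Tensor:
        n_nodes = x.data.shape[0]
        ei, ea = self.with_self_loops(edge_index, edge_attr, n_nodes)
        src, dst = ei
        ea_t = Tensor(ea)
        head_outs = []
        for h in range(self.n_heads):
            proj = x @ self.w[h]                      # (N, D)
            e_proj = ea_t @ self.w_edge[h]            # (E, D)
            logits = (
                gather_rows(proj, src) @ self.a_src[h]
                + gather_rows(proj, dst) @ self.a_dst[h]
                + e_proj @ self.a_edge[h]
            ).leaky_relu(0.2)                         # (E, 1)
            alpha = segment_softmax(logits, dst, n_nodes)
            messages = alpha * gather_rows(proj, src)
            head_outs.append(scatter_sum(messages, dst, n_nodes))
        return concat(head_outs, axis=-1) @ self.proj + self.bias


class Adam:
    """Adam optimizer with decoupled weight decay (AdamW convention)."""

    def __init__(
        self,
        module: Module,
        lr: float = 1e-4,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = module.parameters()
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay and not k.endswith("bias"):
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
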