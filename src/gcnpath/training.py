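"""Mini-batch training with early stopping on validation MSE.

Training runs Adam on the mean squared error of ln(IC50) predictions,
capped at ``max_epochs`` (default 300) with early stopping after
``patience`` (default 10) epochs without validation improvement; the
returned state is the one with the best validation MSE, mirroring the
benchmark protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drugs import DrugGraph
from .model import GCNPathModel
from .nn.autodiff import Tensor
from .nn.layers import Adam

__all__ = ["TrainConfig", "TrainResult", "PairDataset", "train_model"]


@dataclass
class TrainConfig:
    """Optimization settings: Adam with plateau-based learning-rate decay.

    The learning rate halves after ``lr_decay_patience`` epochs without
    validation improvement (down to ``min_lr``); early stopping triggers
    after ``patience`` such epochs.
    """

    max_epochs: int = 300
    patience: int = 10
    lr: float = 1e-4
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 5
    min_lr: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainResult:
    state: dict[str, np.ndarray]
    best_epoch: int
    best_val_mse: float
    epochs_run: int
    history: list[float] = field(default_factory=list)


@dataclass
class PairDataset:
    """Aligned (cell, drug, response) triples over shared feature tables.

    ``scores`` is the scaled pathway-score matrix for the *unique* cells
    (n_cells x n_pathways, row order = ``cell_ids``); ``graphs`` maps the
    unique drugs in ``drug_ids`` order.
    """

    scores: np.ndarray
    cell_ids: list[str]
    graphs: list[DrugGraph]
    drug_ids: list[str]
    cell_idx: np.ndarray
    drug_idx: np.ndarray
    y: np.ndarray

    @classmethod
    def from_frames(
        cls,
        pairs: pd.DataFrame,
        score_matrix: pd.DataFrame,
        drug_graphs: dict[str, DrugGraph],
    ) -> "PairDataset":
        """Build from a (cell_id, drug_id, ln_ic50) frame and feature tables.

        ``score_matrix`` is pathways x samples (columns = cell ids).
        """
        cells = sorted(pairs["cell_id"].unique())
        drugs = sorted(pairs["drug_id"].unique())
        missing_c = [c for c in cells if c not in score_matrix.columns]
        missing_d = [d for d in drugs if d not in drug_graphs]
        if missing_c or missing_d:
            raise ValueError(
                f"features missing for cells {missing_c[:3]} / drugs {missing_d[:3]}"
            )
        c_pos = {c: i for i, c in enumerate(cells)}
        d_pos = {d: i for i, d in enumerate(drugs)}
        return cls(
            scores=score_matrix[cells].to_numpy(dtype=float).T,
            cell_ids=cells,
            graphs=[drug_graphs[d] for d in drugs],
            drug_ids=drugs,
            cell_idx=pairs["cell_id"].map(c_pos).to_numpy(dtype=np.int64),
            drug_idx=pairs["drug_id"].map(d_pos).to_numpy(dtype=np.int64),
            y=pairs["ln_ic50"].to_numpy(dtype=float),
        )

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.cell_idx[idx], self.drug_idx[idx], self.y[idx]


def _eval_mse(model: GCNPathModel, data: PairDataset, idx: np.ndarray | None = None) -> float:
    if idx is None:
        idx = np.arange(len(data))
    preds = model.predict(data.scores, data.cell_idx[idx], data.graphs, data.drug_idx[idx])
    return float(np.mean((preds - data.y[idx]) ** 2))


def train_model(
    model: GCNPathModel,
    train_data: PairDataset,
    val_data: PairDataset,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Fit the model on ``train_data``; early-stop on ``val_data`` MSE.

    Deterministic given ``config.seed``.  Raises on NaN loss with the
    offending epoch/batch in the message.
    """
    config = config or TrainConfig()
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, lr=config.lr, weight_decay=config.weight_decay)
    best_state = model.state_dict()
    best_val = _eval_mse(model, val_data)
    best_epoch = 0
    history = [best_val]
    since_best = 0
    n = len(train_data)
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            ci, di, y = train_data.subset(batch)
            # deduplicate cells and drugs within the batch
            u_cells, ci_local = np.unique(ci, return_inverse=True)
            u_drugs, di_local = np.unique(di, return_inverse=True)
            preds = model.forward_pairs(
                train_data.scores[u_cells],
                ci_local,
                [train_data.graphs[i] for i in u_drugs],
                di_local,
            )
            diff = preds - Tensor(y[:, None])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
        model.eval()
        val_mse = _eval_mse(model, val_data)
        history.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
            if (
                since_best % config.lr_decay_patience == 0
                and opt.lr * config.lr_decay_factor >= config.min_lr
            ):
                opt.lr *= config.lr_decay_factor
    model.load_state_dict(best_state)
    model.eval()
    return TrainResult(
        state=best_state,
        best_epoch=best_epoch,
        best_val_mse=best_val,
        epochs_run=epoch,
        history=history,
    )
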