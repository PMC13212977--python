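"""Model architecture contracts: shapes, determinism, invariances, gradients.

The hand-written backpropagation is validated against central finite
differences; Grad-CAM against a closed-form surrogate whose output is a
fixed linear functional of the first-layer activations.
"""

import numpy as np
import pytest

import gcnpath as gp
from gcnpath.drugs import featurize_drug
from gcnpath.model import GCNPathModel, ModelConfig
from gcnpath.nn.autodiff import Tensor
from gcnpath.pcn import PCNGraph
from gcnpath.training import PairDataset


def small_pcn(n=6, k=2, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i}" for i in range(n)]
    edges = []
    for rel in ("ppi", "grn", "corr"):
        for s in ids:
            for t in rng.choice([x for x in ids if x != s], k, replace=False):
                edges.append((s, t, rel))
    return PCNGraph(ids, edges, k=k)


def small_config(n_pathways=6, **kw):
    defaults = dict(
        n_pathways=n_pathways,
        cell_hidden=[4, 4, 4],
        drug_hidden=[8, 8, 8],
        gat_heads=2,
        cell_embed=16,
        drug_embed=16,
        head_hidden=[16],
        dropout=0.0,
        seed=1,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestShapes:
    def test_default_config_dimensions(self):
        cfg = ModelConfig()
        assert cfg.cell_out_dim == 24
        assert cfg.n_pathways * cfg.cell_out_dim == 7008
        assert cfg.cell_embed == cfg.drug_embed == 256

    def test_cell_forward_batch(self):
        m = GCNPathModel(small_config(), small_pcn())
        out = m.cell_forward(np.random.default_rng(0).normal(size=(4, 6)))
        assert out.shape == (4, 16)

    def test_drug_forward_benzene(self):
        m = GCNPathModel(small_config(), small_pcn())
        emb = m.drug_forward(featurize_drug("c1ccccc1"))
        assert emb.shape == (1, 16)

    def test_single_atom_molecule(self):
        m = GCNPathModel(small_config(), small_pcn())
        emb = m.drug_forward(featurize_drug("C"))
        assert emb.shape == (1, 16) and np.isfinite(emb.data).all()

    def test_edgeless_pcn_still_works(self):
        pcn = PCNGraph([f"P{i}" for i in range(6)], [], k=2)
        m = GCNPathModel(small_config(), pcn)
        out = m.cell_forward(np.zeros((2, 6)))
        assert out.shape == (2, 16) and np.isfinite(out.data).all()

    def test_pathway_count_mismatch_errors(self):
        with pytest.raises(ValueError):
            GCNPathModel(small_config(n_pathways=7), small_pcn(6))


class TestDeterminismAndInvariance:
    def test_eval_forward_deterministic(self):
        m = GCNPathModel(small_config(), small_pcn()).eval()
        scores = np.random.default_rng(2).normal(size=(3, 6))
        g = featurize_drug("CCO")
        a = m.predict(scores, [0, 1, 2], [g], [0, 0, 0])
        b = m.predict(scores, [0, 1, 2], [g], [0, 0, 0])
        np.testing.assert_array_equal(a, b)

    def test_drug_embedding_atom_permutation_invariant(self):
        """SMILES written from different start atoms permute the atom order;
        max pooling makes the embedding invariant (up to float summation
        order in the attention aggregation)."""
        m = GCNPathModel(small_config(), small_pcn()).eval()
        for a, b in [("CCO", "OCC"), ("CC(=O)O", "OC(C)=O"), ("c1ccncc1", "n1ccccc1")]:
            ea = m.drug_forward(featurize_drug(a)).data
            eb = m.drug_forward(featurize_drug(b)).data
            np.testing.assert_allclose(ea, eb, rtol=1e-12, atol=1e-12)

    def test_cell_forward_node_relabeling_equivariance(self):
        """Permuting pathway order, scores and PCN edges together leaves the
        prediction unchanged (weights are re-created per permuted graph with
        the permutation applied to relation adjacencies)."""
        pcn = small_pcn(seed=5)
        cfg = small_config()
        m = GCNPathModel(cfg, pcn).eval()
        rng = np.random.default_rng(3)
        scores = rng.normal(size=6)
        perm = rng.permutation(6)
        ids = pcn.pathway_ids
        perm_ids = [ids[i] for i in perm]
        pcn_perm = PCNGraph(perm_ids, pcn.edges, k=pcn.k)
        m2 = GCNPathModel(cfg, pcn_perm)
        # copy weights, permuting the flatten layer's pathway blocks
        state = m.state_dict()
        c = cfg.cell_out_dim
        w = state["cell_fc.weight"].reshape(6, c, -1)
        inv = np.empty(6, dtype=int)
        for new_pos, old_pos in enumerate(perm):
            inv[old_pos] = new_pos
        state["cell_fc.weight"] = w[perm].reshape(6 * c, -1)
        m2.load_state_dict(state)
        g = featurize_drug("CCO")
        a = m.predict(scores[None, :], [0], [g], [0])
        b = m2.predict(scores[perm][None, :], [0], [g], [0])
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_serialization_round_trip_bitwise(self, tmp_path):
        m = GCNPathModel(small_config(), small_pcn()).eval()
        scores = np.random.default_rng(4).normal(size=(2, 6))
        g = featurize_drug("CC(=O)O")
        before = m.predict(scores, [0, 1], [g], [0, 0])
        m.save(tmp_path / "ckpt.npz")
        loaded = GCNPathModel.load(tmp_path / "ckpt.npz")
        after = loaded.predict(scores, [0, 1], [g], [0, 0])
        np.testing.assert_array_equal(before, after)


class TestPredictionHead:
    def test_zeroed_final_layer_outputs_bias(self):
        m = GCNPathModel(small_config(), small_pcn()).eval()
        final = m.head_layers[-1]
        final.weight.data[:] = 0.0
        final.bias.data[:] = 3.25
        scores = np.random.default_rng(5).normal(size=(3, 6))
        g = featurize_drug("CCN")
        out = m.predict(scores, [0, 1, 2], [g], [0, 0, 0])
        np.testing.assert_allclose(out, 3.25)

    def test_dim_mismatch_errors(self):
        m = GCNPathModel(small_config(), small_pcn())
        with pytest.raises(ValueError):
            m.predict_from_embeddings(Tensor(np.zeros((1, 5))), Tensor(np.zeros((1, 16))))


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_pipeline, tiny_model):
        """Numerical gradient of the MSE loss on a 20-parameter sample agrees
        with backpropagation within 1e-4 relative error."""
        m = tiny_model
        data = PairDataset.from_frames(
            tiny_pipeline["responses"].iloc[:16], tiny_pipeline["scaled"], tiny_pipeline["graphs"]
        )
        ci, di, y = data.cell_idx, data.drug_idx, data.y
        uc, cl = np.unique(ci, return_inverse=True)
        ud, dl = np.unique(di, return_inverse=True)
        graphs = [data.graphs[i] for i in ud]

        def loss_value():
            pred = m.predict(data.scores[uc], cl, graphs, dl)
            return float(np.mean((pred - y) ** 2))

        m.eval()
        m.zero_grad()
        pred = m.forward_pairs(data.scores[uc], cl, graphs, dl)
        diff = pred - Tensor(y[:, None])
        (diff * diff).mean().backward()
        params = m.parameters()
        rng = np.random.default_rng(9)
        names = rng.choice(sorted(params), size=10, replace=False)
        eps = 1e-6
        for name in names:
            p = params[name]
            for _ in range(2):
                flat = int(rng.integers(p.data.size))
                orig = p.data.flat[flat]
                p.data.flat[flat] = orig + eps
                lp = loss_value()
                p.data.flat[flat] = orig - eps
                lm = loss_value()
                p.data.flat[flat] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = p.grad.flat[flat]
                assert abs(numeric - analytic) <= 1e-4 * max(1.0, abs(numeric) + abs(analytic)), name


class TestGradCam:
    def test_contract(self, tiny_pipeline, tiny_model):
        scaled = tiny_pipeline["scaled"]
        g = next(iter(tiny_pipeline["graphs"].values()))
        att = tiny_model.grad_cam(scaled.iloc[:, 0].to_numpy(), g, top_k=5)
        assert len(att.importance) == 10
        assert (att.importance >= 0).all()
        assert len(att.top_k) == 5

    @pytest.mark.parametrize("weighting", ["channel_mean", "elementwise"])
    def test_linear_surrogate_closed_form(self, weighting):
        """If the network output is a fixed linear functional W of the first
        cell-layer activations A, attribution reduces to analytic formulas:
        channel_mean -> ReLU(A @ mean_p(W)); elementwise -> ReLU(sum_k W*A)."""
        pcn = small_pcn(seed=11)
        cfg = small_config()
        m = GCNPathModel(cfg, pcn).eval()
        rng = np.random.default_rng(12)
        w_lin = rng.normal(size=(6, 4))

        class Surrogate(GCNPathModel):
            def forward_pairs(self, scores, cell_idx, graphs, drug_idx, keep_activations=False):
                x = Tensor(np.asarray(scores)[:, :, None])
                h = self.cell_layers[0](x, self.adjacencies).elu()
                self._first_cell_activation = h
                return (h * Tensor(w_lin[None, :, :])).sum(axis=2).sum(axis=1, keepdims=True)

        s = Surrogate(cfg, pcn)
        s.load_state_dict(m.state_dict())
        scores = rng.normal(size=6)
        g = featurize_drug("CCO")
        att = s.grad_cam(scores, g, target="response", weighting=weighting)
        act = s._first_cell_activation.data[0]
        if weighting == "channel_mean":
            expected = np.maximum(act @ w_lin.mean(axis=0), 0.0)
        else:
            expected = np.maximum((act * w_lin).sum(axis=1), 0.0)
        np.testing.assert_allclose(att.importance, expected, rtol=1e-10)

    def test_sensitivity_target_flips_gradient_sign(self):
        """The sensitivity target attributes from -prediction: its pre-ReLU
        importances are the negatives of the response target's."""
        pcn = small_pcn(seed=13)
        m = GCNPathModel(small_config(), pcn).eval()
        scores = np.random.default_rng(14).normal(size=6)
        g = featurize_drug("CCO")
        sens = m.grad_cam(scores, g, target="sensitivity")
        resp = m.grad_cam(scores, g, target="response")
        both_positive = (sens.importance > 0) & (resp.importance > 0)
        assert not both_positive.any()

    def test_symmetric_pathways_equal_importance_under_channel_mean(self):
        """Two pathways with identical activations and wiring score equally
        under channel-mean weighting (shared alpha; element-wise weighting
        may distinguish them through their pathway-specific head weights)."""
        ids = ["A", "B", "C"]
        edges = [("A", "C", "ppi"), ("B", "C", "ppi")]
        pcn = PCNGraph(ids, edges, k=1)
        m = GCNPathModel(small_config(n_pathways=3), pcn).eval()
        scores = np.array([0.7, 0.7, -0.2])
        att = m.grad_cam(scores, featurize_drug("CCO"), weighting="channel_mean")
        imp = dict(zip(att.pathway_ids, att.importance))
        assert imp["A"] == pytest.approx(imp["B"], rel=1e-12)
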