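import numpy as np
import pandas as pd
import pytest

from gcnpath.evaluation import (
    compare_models,
    compute_metrics,
    entity_statistics,
    make_splits,
    responder_analysis,
)


def grid_table(n_cells=12, n_drugs=12, seed=0):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n_cells)]
    drugs = [f"d{j}" for j in range(n_drugs)]
    rows = [
        {"cell_id": c, "drug_id": d, "ln_ic50": float(rng.normal()), "source": "SYNTHETIC"}
        for c in cells
        for d in drugs
    ]
    return pd.DataFrame(rows)


class TestMakeSplits:
    @pytest.mark.parametrize(
        "scenario,n_folds",
        [("unblinded", 10), ("cell_blind", 10), ("drug_blind", 10), ("strict_blind", 25)],
    )
    def test_fold_counts(self, scenario, n_folds):
        plan = make_splits(grid_table(), scenario, seed=1)
        assert len(plan.folds) == n_folds

    def test_unblinded_partition_arithmetic(self):
        df = grid_table(10, 10)  # 100 pairs
        plan = make_splits(df, "unblinded", seed=3)
        for f in plan.folds:
            assert len(f.test) == 10 and len(f.val) == 10 and len(f.train) == 80
        all_test = np.concatenate([f.test for f in plan.folds])
        assert sorted(all_test) == list(range(100))  # each pair tested once

    def test_fold_sets_disjoint_within_fold(self):
        plan = make_splits(grid_table(), "unblinded", seed=5)
        for f in plan.folds:
            assert not (set(f.train) & set(f.val) | set(f.train) & set(f.test) | set(f.val) & set(f.test))

    @pytest.mark.parametrize("scenario,col", [("cell_blind", "cell_id"), ("drug_blind", "drug_id")])
    def test_blind_entity_disjointness(self, scenario, col):
        df = grid_table()
        for seed in range(25):
            plan = make_splits(df, scenario, seed=seed)
            for f in plan.folds:
                held_out = set(df.iloc[f.test][col])
                seen = set(df.iloc[f.train][col]) | set(df.iloc[f.val][col])
                assert not held_out & seen

    def test_strict_blind_block_structure(self):
        df = grid_table(10, 10)
        plan = make_splits(df, "strict_blind", seed=7)
        # every (cell part, drug part) block is the test block exactly once
        cp = plan.meta["cell_parts"]
        dp = plan.meta["drug_parts"]
        blocks = set()
        for f in plan.folds:
            sub = df.iloc[f.test]
            cparts = {cp[c] for c in sub["cell_id"]}
            dparts = {dp[d] for d in sub["drug_id"]}
            assert len(cparts) == 1 and len(dparts) == 1
            blocks.add((cparts.pop(), dparts.pop()))
            # both entity axes blind
            assert not set(sub["cell_id"]) & set(df.iloc[f.train]["cell_id"])
            assert not set(sub["drug_id"]) & set(df.iloc[f.train]["drug_id"])
        assert blocks == {(i, j) for i in range(5) for j in range(5)}

    def test_strict_blind_10x10_test_size(self):
        df = grid_table(10, 10)
        plan = make_splits(df, "strict_blind", seed=2)
        assert all(len(f.test) == 4 for f in plan.folds)  # 2 cells x 2 drugs

    def test_too_few_entities_errors(self):
        df = grid_table(4, 12)
        with pytest.raises(ValueError):
            make_splits(df, "cell_blind", seed=0)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.rmse == 0.0 and rep.pcc == pytest.approx(1.0) and rep.scc == pytest.approx(1.0)

    def test_hand_computed_rmse(self):
        rep = compute_metrics([0.0, 0.0], [3.0, 4.0])
        assert rep.rmse == pytest.approx(np.sqrt(12.5))

    def test_monotone_nonlinear_scc_one_pcc_below(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = np.exp(truth)
        rep = compute_metrics(pred, truth)
        assert rep.scc == pytest.approx(1.0)
        assert rep.pcc < 1.0

    def test_zero_variance_truth(self):
        rep = compute_metrics([1.0, 2.0], [3.0, 3.0])
        assert np.isnan(rep.pcc) and np.isnan(rep.scc)
        assert rep.rmse > 0

    def test_per_group_min_size(self):
        pred = np.arange(8.0)
        truth = pred + 0.1
        groups = np.array(["a"] * 5 + ["b"] * 2 + ["c"])
        rep = compute_metrics(pred, truth, group_by=groups)
        assert list(rep.per_group["group"]) == ["a"]  # b, c below min size 3


class TestCompareModels:
    def test_exact_enumerated_p(self):
        # A entirely below B: P(U=0) among C(4,2)=6 orderings -> 1/6
        p = compare_models([1.0, 2.0, 1.5], [3.0, 4.0, 3.5], better="lower")
        # 3v3 exact: most extreme ordering has p = 1/C(6,3) = 1/20
        assert p == pytest.approx(1 / 20)

    def test_two_vs_two_exact_sixth(self):
        from gcnpath.evaluation import mannwhitney_one_tailed

        p = mannwhitney_one_tailed([1.0, 2.0], [3.0, 4.0], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_no_evidence_when_equal_distributions(self):
        p = compare_models([1.0, 2.0, 3.0], [1.5, 2.5, 0.5], better="lower")
        assert p >= 0.4

    def test_swapped_arguments_complementary(self):
        from gcnpath.evaluation import mannwhitney_one_tailed

        a, b = [1.0, 2.0], [3.0, 4.0]
        p_less = mannwhitney_one_tailed(a, b, "less")
        p_greater = mannwhitney_one_tailed(b, a, "less")
        # exact-test symmetry: p_swapped = 1 - p + P(U = u_obs); here the
        # extreme ordering has point mass 1/6
        assert p_greater == pytest.approx(1.0 - p_less + 1 / 6)

    def test_identical_constant_samples_convention(self):
        with pytest.warns(UserWarning, match="0.5"):
            p = compare_models([1.0] * 3, [1.0] * 3)
        assert p == 0.5

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            compare_models([1.0, 2.0], [3.0, 4.0, 5.0])


class TestResponderAnalysis:
    def test_enumerated_example(self):
        effect, p = responder_analysis([1.0, 2.0], [3.0, 4.0])
        assert effect == pytest.approx(-2.0)
        assert p == pytest.approx(1 / 6)

    def test_identical_distributions_zero_effect(self):
        effect, _ = responder_analysis([1.0, 2.0], [1.0, 2.0])
        assert effect == 0.0

    def test_inconsistent_direction(self):
        effect, p = responder_analysis([5.0, 6.0], [1.0, 2.0])
        assert effect > 0 and p > 0.5

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            responder_analysis([], [1.0])


class TestEntityStatistics:
    def test_hand_computed_moments(self):
        df = pd.DataFrame(
            {"cell_id": "c", "drug_id": ["d"] * 3, "ln_ic50": [0.0, 0.0, 3.0], "source": "X"}
        )
        stats = entity_statistics(df, by="drug")
        row = stats.iloc[0]
        assert row["count"] == 3
        assert row["mean"] == pytest.approx(1.0)
        assert row["std"] == pytest.approx(np.sqrt(3.0))
        assert np.isnan(row["bimodality"])  # n < 4

    def test_constant_values_zero_std(self):
        df = pd.DataFrame(
            {"cell_id": "c", "drug_id": ["d"] * 5, "ln_ic50": [2.0] * 5, "source": "X"}
        )
        stats = entity_statistics(df, by="drug")
        assert stats.iloc[0]["std"] == 0.0

    def test_density_coverage_approaches_one_for_global_distribution(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=2000)
        df = pd.DataFrame(
            {
                "cell_id": "c",
                "drug_id": np.repeat(["d1", "d2"], 1000),
                "ln_ic50": values,
                "source": "X",
            }
        )
        stats = entity_statistics(df, by="drug").set_index("drug_id")
        # both entities drawn from the global distribution: coverage near 1
        assert stats.loc["d1", "density_coverage"] > 0.9
        assert stats.loc["d2", "density_coverage"] > 0.9

    def test_bimodal_entity_scores_higher(self):
        rng = np.random.default_rng(1)
        uni = rng.normal(0, 1, 300)
        bim = np.concatenate([rng.normal(-3, 0.3, 150), rng.normal(3, 0.3, 150)])
        df = pd.DataFrame(
            {
                "cell_id": "c",
                "drug_id": np.repeat(["uni", "bim"], 300),
                "ln_ic50": np.concatenate([uni, bim]),
                "source": "X",
            }
        )
        stats = entity_statistics(df, by="drug").set_index("drug_id")
        assert stats.loc["bim", "bimodality"] > stats.loc["uni", "bimodality"]
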