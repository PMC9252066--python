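import numpy as np
import pandas as pd
import pytest

from genefam.core_model import ValidationError
from genefam.expression_profiles import (
    condition_average,
    ddct_fold_change,
    hcluster_rows,
    high_expression_count,
    percent_of_max,
)
from genefam.synthetic_data import simulate_expression


class TestPercentOfMax:
    def test_row_normalization(self):
        m = pd.DataFrame([[10.0, 50.0, 100.0]], index=["g"], columns=list("abc"))
        pct, flagged = percent_of_max(m)
        assert pct.loc["g"].tolist() == [10.0, 50.0, 100.0]
        assert flagged == []

    def test_constant_row(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc"))
        pct, _ = percent_of_max(m)
        assert (pct.loc["g"] == 100.0).all()

    def test_zero_row_flagged(self):
        m = pd.DataFrame([[0.0, 0.0]], index=["g"], columns=list("ab"))
        pct, flagged = percent_of_max(m)
        assert flagged == ["g"]
        assert pct.loc["g"].isna().all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(1, 100, size=(5, 4)))
        pct1, _ = percent_of_max(m)
        pct2, _ = percent_of_max(m * 7.3)
        pd.testing.assert_frame_equal(pct1, pct2)

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            percent_of_max(pd.DataFrame([[-1.0]]))


class TestConditionAverage:
    def test_group_mean_over_cells(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["s1", "s2"])
        avg = condition_average(m, {"s1": "g", "s2": "g"})
        assert avg["g"] == 2.5

    def test_single_cell_group(self):
        m = pd.DataFrame([[7.0]], columns=["s1"])
        assert condition_average(m, {"s1": "g"})["g"] == 7.0

    def test_unassigned_sample_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], columns=["s1", "s2"])
        with pytest.raises(ValidationError):
            condition_average(m, {"s1": "g"})

    def test_identical_values_any_grouping(self):
        m = pd.DataFrame(np.full((3, 4), 9.0), columns=list("abcd"))
        avg = condition_average(m, {"a": "x", "b": "x", "c": "y", "d": "y"})
        assert (avg == 9.0).all()


class TestHighExpression:
    def test_counting_above_threshold(self):
        pct = pd.DataFrame(
            {"t1": [70.0, 61.0, 59.0]}, index=["g1", "g2", "g3"]
        )
        counts = high_expression_count(pct, {"t1": "root"}, threshold=60.0)
        assert counts["root"] == 2

    def test_threshold_100_boundary(self):
        pct = pd.DataFrame({"t1": [100.0, 99.0]}, index=["g1", "g2"])
        counts = high_expression_count(pct, {"t1": "root"}, threshold=100.0)
        assert counts["root"] == 0

    def test_empty_matrix(self):
        pct = pd.DataFrame(columns=["t1"])
        counts = high_expression_count(pct, {"t1": "root"})
        assert counts["root"] == 0


class TestClustering:
    def test_first_merge_is_closest_pair(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]], index=["r1", "r2", "r3"]
        )
        link, order = hcluster_rows(m)
        first = sorted(link[0][:2].astype(int))
        assert first == [0, 1]  # Manhattan distance 1 beats the rest
        assert link[0][2] == pytest.approx(1.0)

    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("abc"))
        link, _ = hcluster_rows(m)
        assert link[0][2] == 0.0

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.uniform(0, 10, size=(6, 3)), index=[f"g{i}" for i in range(6)])
        _, order1 = hcluster_rows(m)
        perm = m.iloc[[3, 1, 5, 0, 2, 4]]
        _, order2 = hcluster_rows(perm)
        # same leaves adjacent regardless of input order
        assert set(order1) == set(order2)

    def test_planted_two_cluster_structure_separates(self):
        effects = np.array(
            [[10.0, 0.1], [10.0, 0.1], [0.1, 10.0], [0.1, 10.0]]
        )
        matrix, grouping, _, _ = simulate_expression(
            4, {"c1": 2, "c2": 2}, effects=effects, noise_sd=0.0, seed=3
        )
        link, order = hcluster_rows(matrix)
        pos = {g: i for i, g in enumerate(order)}
        left = {pos["G1"], pos["G2"]}
        right = {pos["G3"], pos["G4"]}
        assert max(left) < min(right) or max(right) < min(left)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            hcluster_rows(pd.DataFrame([[1.0, 2.0]]))


def _cq_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "condition", "replicate", "cq_target", "cq_reference"]
    )


class TestDdct:
    def test_no_change_gives_unity(self):
        cq = _cq_frame(
            [
                ["g", "control", 1, 25.0, 20.0],
                ["g", "treated", 1, 26.0, 21.0],
            ]
        )
        res = ddct_fold_change(cq)
        assert res.loc[0, "fold_change"] == pytest.approx(1.0)

    def test_two_cycle_shift_gives_fourfold(self):
        cq = _cq_frame(
            [
                ["g", "control", 1, 25.0, 20.0],
                ["g", "treated", 1, 23.0, 20.0],
            ]
        )
        res = ddct_fold_change(cq)
        assert res.loc[0, "fold_change"] == pytest.approx(4.0)

    def test_zero_variance_replicates(self):
        cq = _cq_frame(
            [["g", "control", 1, 25.0, 20.0]]
            + [["g", "treated", r, 24.0, 20.0] for r in (1, 2, 3)]
        )
        res = ddct_fold_change(cq)
        assert res.loc[0, "fold_change"] == pytest.approx(2.0)
        assert res.loc[0, "se"] == 0.0

    def test_reference_shift_invariance(self):
        base = _cq_frame(
            [
                ["g", "control", 1, 25.0, 20.0],
                ["g", "control", 2, 25.2, 20.1],
                ["g", "treated", 1, 23.0, 20.0],
                ["g", "treated", 2, 23.1, 20.2],
            ]
        )
        shifted = base.copy()
        mask = shifted["condition"] == "treated"
        shifted.loc[mask, ["cq_target", "cq_reference"]] += 3.0
        r1 = ddct_fold_change(base)
        r2 = ddct_fold_change(shifted)
        assert r1.loc[0, "fold_change"] == pytest.approx(r2.loc[0, "fold_change"])

    def test_missing_reference_rejected(self):
        cq = _cq_frame(
            [["g", "control", 1, 25.0, np.nan], ["g", "treated", 1, 23.0, 20.0]]
        )
        with pytest.raises(ValidationError):
            ddct_fold_change(cq)

    @pytest.mark.parametrize("fold", [0.25, 1.0, 4.0])
    def test_planted_fold_change_recovery(self, fold):
        # σ = 0.1 cycles, 20 seeded replicates: mean recovery within 15%
        recovered = []
        for seed in range(20):
            _, _, cq, _ = simulate_expression(
                1,
                {"c": 1},
                cq_fold_changes={"G1": fold},
                noise_sd=0.1,
                seed=5000 + seed,
            )
            res = ddct_fold_change(cq)
            recovered.append(float(res.loc[0, "fold_change"]))
        assert np.mean(recovered) == pytest.approx(fold, rel=0.15)
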