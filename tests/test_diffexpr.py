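"""Differential-expression stage: Welch test, BH, thresholds, intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regloop.diffexpr import (
    GENE_POLICY,
    MIRNA_POLICY,
    ExpressionMatrix,
    ThresholdPolicy,
    apply_thresholds,
    bh_adjust,
    consistency_filter,
    count_filter,
    de_two_group,
    intersect_consistent,
)


def matrix_from(values, case, ctrl, modality="intensity"):
    cols = [f"c{i}" for i in range(case)] + [f"n{i}" for i in range(ctrl)]
    groups = {c: ("case" if c.startswith("c") else "control") for c in cols}
    df = pd.DataFrame(values, columns=cols,
                      index=[f"F{i}" for i in range(len(values))])
    return ExpressionMatrix(df, groups, modality)


class TestWelch:
    def test_matches_hand_computed_welch_formula(self):
        """p equals the textbook Welch t with Welch-Satterthwaite df."""
        vals = [[1.0, 2.0, 3.0, 5.0, 6.0, 9.0],
                [0.1, 0.2, 0.15, 4.0, 4.1, 4.3]]
        mat = matrix_from(vals, 3, 3)
        res = de_two_group(mat)
        from scipy import stats

        for i, row in enumerate(vals):
            x, y = np.array(row[:3]), np.array(row[3:])
            vx, vy = x.var(ddof=1), y.var(ddof=1)
            se2 = vx / 3 + vy / 3
            t = (x.mean() - y.mean()) / np.sqrt(se2)
            df = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 3) ** 2 / 2)
            p = 2 * stats.t.sf(abs(t), df)
            assert res["p_raw"].iloc[i] == pytest.approx(p, rel=1e-12)
            assert res["log2fc"].iloc[i] == pytest.approx(x.mean() - y.mean())

    def test_identical_groups_give_zero_lfc_and_no_direction(self):
        mat = matrix_from([[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]], 3, 3)
        res = apply_thresholds(de_two_group(mat), GENE_POLICY)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0
        assert res["direction"].iloc[0] == "none"

    def test_case_scale_shift_moves_lfc_exactly(self):
        """Multiplying case intensities by 4 (adding 2 in log2) shifts log2fc by +2."""
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=(5, 8))
        m1 = matrix_from(base.tolist(), 4, 4)
        shifted = base.copy()
        shifted[:, :4] += 2.0
        m2 = matrix_from(shifted.tolist(), 4, 4)
        r1, r2 = de_two_group(m1), de_two_group(m2)
        assert np.allclose(r2["log2fc"] - r1["log2fc"], 2.0)

    def test_fewer_than_two_samples_per_group_rejected(self):
        mat = matrix_from([[1.0, 2.0, 3.0]], 1, 2)
        with pytest.raises(ValueError, match="2 samples"):
            de_two_group(mat)

    def test_count_modality_tested_on_log2_cpm(self):
        """Count matrices are normalised per library before testing."""
        vals = [[100, 200, 100, 200], [900, 1800, 900, 1800]]
        mat = matrix_from(vals, 2, 2, modality="count")
        res = de_two_group(mat)
        # both features have identical CPM in all samples -> no change
        assert np.allclose(res["log2fc"], 0.0)


class TestBH:
    def test_hand_computed_step_up_cases(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        # a hand-worked non-degenerate case: n=4
        # sorted p: .005 .04 .06 .6 -> scaled .02 .08 .08 .6 -> step-up mins
        assert bh_adjust([0.04, 0.6, 0.005, 0.06]) == pytest.approx(
            [0.08, 0.6, 0.02, 0.08]
        )

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_properties(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestThresholds:
    def test_gene_policy_pass(self):
        df = pd.DataFrame(
            {"feature_id": ["G1"], "log2fc": [2.5], "p_raw": [1e-7],
             "p_adj": [1e-6], "direction": ["none"], "passed": [False]}
        )
        out = apply_thresholds(df, GENE_POLICY)
        assert bool(out["passed"].iloc[0]) and out["direction"].iloc[0] == "up"

    def test_boundary_fold_change_is_strict(self):
        df = pd.DataFrame(
            {"feature_id": ["G1"], "log2fc": [2.0], "p_raw": [1e-9],
             "p_adj": [1e-8], "direction": ["none"], "passed": [False]}
        )
        assert not apply_thresholds(df, GENE_POLICY)["passed"].iloc[0]

    def test_mirna_policy_uses_raw_p(self):
        df = pd.DataFrame(
            {"feature_id": ["m1"], "log2fc": [-1.5], "p_raw": [0.01],
             "p_adj": [0.2], "direction": ["none"], "passed": [False]}
        )
        out = apply_thresholds(df, MIRNA_POLICY)
        assert bool(out["passed"].iloc[0]) and out["direction"].iloc[0] == "down"

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"feature_id": [f"G{i}" for i in range(50)],
             "log2fc": rng.normal(0, 3, 50),
             "p_raw": rng.random(50) * 1e-4,
             "p_adj": rng.random(50) * 1e-3,
             "direction": "none", "passed": False}
        )
        once = apply_thresholds(df, GENE_POLICY)
        twice = apply_thresholds(once, GENE_POLICY)
        pd.testing.assert_frame_equal(once, twice)

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            ThresholdPolicy(fc_min=0.5)
        with pytest.raises(ValueError):
            ThresholdPolicy(p_max=0.0)


class TestCountFilter:
    def make(self, rows):
        return matrix_from(rows, 2, 2, modality="count")

    def test_feature_above_floor_in_one_sample_retained(self):
        mat = self.make([[150, 0, 0, 0], [50, 60, 70, 80]])
        out = count_filter(mat, MIRNA_POLICY)
        assert out.feature_ids == ["F0"]

    def test_exactly_at_floor_removed(self):
        mat = self.make([[100, 100, 100, 100]])
        assert count_filter(mat, MIRNA_POLICY).feature_ids == []

    def test_min_count_zero_keeps_any_positive(self):
        mat = self.make([[1, 0, 0, 0], [0, 0, 0, 0]])
        policy = ThresholdPolicy(fc_min=2, p_max=0.05, min_count=0)
        assert count_filter(mat, policy).feature_ids == ["F0"]

    def test_intensity_rejected(self):
        mat = matrix_from([[1.0, 2.0, 3.0, 4.0]], 2, 2)
        with pytest.raises(ValueError, match="count"):
            count_filter(mat, MIRNA_POLICY)


def passed_frame(items):
    rows = [
        {"feature_id": f, "log2fc": 1.0 if d == "up" else -1.0,
         "p_raw": 0.0, "p_adj": 0.0, "direction": d, "passed": d != "none"}
        for f, d in items
    ]
    return pd.DataFrame(rows)


class TestIntersect:
    def test_same_trend_kept_opposite_reported(self):
        a = passed_frame([("G1", "up"), ("G2", "down")])
        b = passed_frame([("G1", "up"), ("G2", "up")])
        conc, disc = intersect_consistent(a, b)
        assert conc.to_dict("records") == [{"feature_id": "G1", "direction": "up"}]
        assert disc == ["G2"]

    def test_disjoint_sets_empty(self):
        conc, disc = intersect_consistent(
            passed_frame([("G1", "up")]), passed_frame([("G2", "up")])
        )
        assert len(conc) == 0 and disc == []

    def test_self_intersection_identity(self):
        a = passed_frame([("G1", "up"), ("G2", "down"), ("G3", "none")])
        conc, disc = intersect_consistent(a, a)
        assert set(conc["feature_id"]) == {"G1", "G2"} and disc == []

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(3)
        feats = [f"G{i}" for i in range(100)]
        def rand_frame():
            return passed_frame(
                [(f, rng.choice(["up", "down", "none"])) for f in feats]
            )
        a, b = rand_frame(), rand_frame()
        conc, disc = intersect_consistent(a, b)
        da = {f: d for f, d in zip(a.feature_id, a.direction) if d != "none"}
        db = {f: d for f, d in zip(b.feature_id, b.direction) if d != "none"}
        both = set(da) & set(db)
        assert set(conc["feature_id"]) == {f for f in both if da[f] == db[f]}
        assert set(disc) == {f for f in both if da[f] != db[f]}


class TestConsistencyFilter:
    def test_noise_free_up_feature_retained(self):
        mat = matrix_from([[9, 9, 9, 1, 1, 1]], 3, 3)
        cand = pd.DataFrame({"feature_id": ["F0"], "direction": ["up"]})
        assert consistency_filter(mat, cand)["feature_id"].tolist() == ["F0"]

    def test_split_case_samples_removed(self):
        # case half above, half below the pooled median
        mat = matrix_from([[9, 9, 1, 1, 5, 5, 5, 5]], 4, 4)
        cand = pd.DataFrame({"feature_id": ["F0"], "direction": ["up"]})
        assert len(consistency_filter(mat, cand, 0.8)) == 0

    def test_matches_hand_count_on_fixed_vector(self):
        # pooled median of the 10 values is 5; case above-median count = 4/5
        vals = [[8, 7, 9, 6, 2, 5, 5, 4, 3, 1]]
        mat = matrix_from(vals, 5, 5)
        cand = pd.DataFrame({"feature_id": ["F0"], "direction": ["up"]})
        assert len(consistency_filter(mat, cand, 0.8)) == 1  # 0.8 of 5 = 4 -> kept
        assert len(consistency_filter(mat, cand, 0.9)) == 0

    def test_empty_case_group_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["F0"], columns=["a", "b"])
        mat = ExpressionMatrix(df, {"a": "control", "b": "control"})
        cand = pd.DataFrame({"feature_id": ["F0"], "direction": ["up"]})
        with pytest.raises(ValueError, match="case"):
            consistency_filter(mat, cand)


class TestExpressionMatrix:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["a", "a"], columns=["s1"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(df, {"s1": "case"})

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([[-1]], index=["f"], columns=["s"])
        with pytest.raises(ValueError, match="negative"):
            ExpressionMatrix(df, {"s": "case"}, "count")
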