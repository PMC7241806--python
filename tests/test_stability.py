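"""Classic stability algorithms against independent hand oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from refstab.datamodel import ValidationError
from refstab.stability import (
    bestkeeper,
    combination_stability,
    comparative_delta_cq,
    genorm,
    normfinder,
)
from tests.conftest import make_rq


def random_rq(seed, n=8, g=4, groups=None):
    rng = np.random.default_rng(seed)
    return make_rq(rng.lognormal(0.0, 0.8, size=(n, g)),
                   [f"G{i}" for i in range(g)], groups=groups)


class TestGenorm:
    def test_toy_matrix_hand_oracle(self, toy_rq_abc):
        """A=(1,2,4,8), B=2A, C=1: M from explicitly enumerated pairwise SDs."""
        # independent oracle: all three pairwise log2-ratio SDs by hand
        sd_ab = 0.0  # log2(A/B) = -1 everywhere
        sd_ac = float(np.std([0.0, 1.0, 2.0, 3.0], ddof=1))  # log2(A/C)
        sd_bc = float(np.std([1.0, 2.0, 3.0, 4.0], ddof=1))  # log2(B/C)
        res = genorm(toy_rq_abc)
        assert res.m_values["A"] == pytest.approx((sd_ab + sd_ac) / 2)
        assert res.m_values["A"] == pytest.approx(0.6455, abs=5e-5)
        assert res.m_values["B"] == pytest.approx((sd_ab + sd_bc) / 2)
        assert res.m_values["C"] == pytest.approx((sd_ac + sd_bc) / 2)
        assert res.m_values["C"] == pytest.approx(1.2910, abs=5e-5)
        assert res.elimination_order[0] == "C"
        assert res.final_pair == ("A", "B")

    def test_identical_genes_zero_mutual_ratio(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(0, 1, size=6)
        vals = np.column_stack([a, a, rng.lognormal(0, 1, size=6)])
        res = genorm(make_rq(vals, ["A", "A2", "C"]))
        # identical genes share every ratio except the zero-SD mutual one
        assert res.m_values["A"] == res.m_values["A2"]
        assert res.final_pair == ("A", "A2")

    def test_requires_three_genes(self):
        with pytest.raises(ValidationError, match="3 genes"):
            genorm(make_rq(np.ones((4, 2)), ["A", "B"]))

    @given(shift=st.floats(-4.0, 4.0), seed=st.integers(0, 50))
    def test_log_shift_invariance(self, shift, seed):
        """Scaling one gene's RQ by a constant leaves every M unchanged."""
        rq = random_rq(seed)
        shifted = rq.values.copy()
        shifted["G1"] = shifted["G1"] * (2.0**shift)
        m1 = genorm(rq).m_values
        m2 = genorm(make_rq(shifted.to_numpy(), shifted.columns)).m_values
        np.testing.assert_allclose(m1, m2, rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_m_equals_delta_cq_score_on_shared_scale(self, seed):
        """Both are mean pairwise SDs: on Cq := -log2 RQ they coincide."""
        rq = random_rq(seed, n=10, g=5)
        m = genorm(rq).m_values
        pseudo_cq = -np.log2(rq.values)
        dq = comparative_delta_cq(pseudo_cq).scores
        np.testing.assert_allclose(m, dq.reindex(m.index), rtol=1e-9)

    def test_pairwise_variation_definition(self, sim_rq):
        """V_2 equals the SD of log2(NF_2 / NF_3) recomputed independently."""
        res = genorm(sim_rq)
        top = res.ranking
        log2rq = np.log2(sim_rq.values)
        nf2 = log2rq[top[:2]].mean(axis=1)
        nf3 = log2rq[top[:3]].mean(axis=1)
        assert res.pairwise_variation[2] == pytest.approx((nf2 - nf3).std(ddof=1))


class TestNormFinder:
    def test_degenerate_identical_data(self):
        vals = np.tile([[2.0, 4.0, 8.0]], (6, 1))
        res = normfinder(make_rq(vals, ["A", "B", "C"]))
        np.testing.assert_allclose(res.stability, 0.0, atol=1e-5)

    def test_two_group_shift_hand_oracle(self):
        """3 genes, 2 groups x 3 samples, +1 log2 shift on gene A in group 2.

        All intermediate quantities are recomputed here step by step with
        independent numpy arithmetic and compared exactly.
        """
        rng = np.random.default_rng(42)
        y = 20.0 + rng.normal(0.0, 0.2, size=(6, 3))
        y[3:, 0] += 1.0  # group-specific shift on gene A
        rq = make_rq(2.0**y, ["A", "B", "C"], groups=["g1"] * 3 + ["g2"] * 3)
        res = normfinder(rq, rq.groups)

        # --- independent oracle -------------------------------------------
        G = 3
        z = y - y.mean(axis=1, keepdims=True)
        groups = [slice(0, 3), slice(3, 6)]
        d = np.array([z[sl].mean(axis=0) - z.mean(axis=0) for sl in groups])
        s2 = np.array([z[sl].var(axis=0, ddof=1) for sl in groups])
        sigma2 = np.maximum(1e-12, s2 - s2.mean(axis=1, keepdims=True) / G)
        var_d = sigma2 / 3.0
        gamma2 = max(0.0, (d**2).mean() * G / (G - 1) - var_d.mean())
        d_sh = d * gamma2 / (gamma2 + var_d)
        stab = (np.abs(d_sh) + np.sqrt(var_d)).mean(axis=0)
        # -------------------------------------------------------------------

        np.testing.assert_allclose(res.group_differences.to_numpy(), d.T, rtol=1e-12)
        np.testing.assert_allclose(res.group_variances.to_numpy(), sigma2.T, rtol=1e-12)
        assert res.gamma2 == pytest.approx(gamma2, rel=1e-12)
        np.testing.assert_allclose(res.shrunken_differences.to_numpy(), d_sh.T, rtol=1e-12)
        np.testing.assert_allclose(res.stability.to_numpy(), stab, rtol=1e-12)
        # the shifted gene has the largest intergroup difference and worst score
        assert res.stability.idxmax() == "A"
        assert np.abs(res.group_differences.loc["A"]).max() == np.abs(d).max()

    def test_single_group_reduces_to_centered_variance(self):
        rq = random_rq(9, n=12, g=4)
        res = normfinder(rq)
        y = np.log2(rq.values.to_numpy())
        z = y - y.mean(axis=1, keepdims=True)
        s2 = z.var(axis=0, ddof=1)
        oracle = np.sqrt(np.maximum(1e-12, s2 - s2.mean() / 4))
        np.testing.assert_allclose(res.stability, oracle, rtol=1e-10)
        assert res.single_group

    def test_best_pair_minimizes_combination_stability(self):
        rq = random_rq(5, n=12, g=4, groups=["a"] * 6 + ["b"] * 6)
        res = normfinder(rq, rq.groups)
        from itertools import combinations

        vals = {p: combination_stability(res, p) for p in combinations(rq.genes, 2)}
        assert res.best_pair == min(vals, key=vals.get)
        assert res.best_pair_stability == pytest.approx(min(vals.values()))

    def test_single_sample_group_excluded_with_warning(self):
        rq = random_rq(11, n=7, g=3, groups=["a"] * 3 + ["b"] * 3 + ["c"])
        with pytest.warns(UserWarning, match="single sample"):
            res = normfinder(rq, rq.groups)
        assert res.group_differences.shape[1] == 2


class TestBestKeeper:
    def test_mad_hand_example(self):
        """Cq (20, 21, 22): arithmetic mean 21, MAD (1+0+1)/3."""
        wide = pd.DataFrame({"A": [20.0, 21.0, 22.0], "B": [20.0, 20.5, 21.0]})
        res = bestkeeper(wide)
        assert res.summary.loc["A", "arith_mean_cq"] == pytest.approx(21.0)
        assert res.summary.loc["A", "sd_cq"] == pytest.approx(2.0 / 3.0)

    def test_perfect_correlation_with_index(self):
        v = np.array([20.0, 21.0, 23.0, 24.0])
        wide = pd.DataFrame({"A": v, "B": v, "C": v})
        res = bestkeeper(wide)
        np.testing.assert_allclose(res.summary["r"], 1.0)
        np.testing.assert_allclose(res.index, v)

    def test_reliability_cutoff_one_cycle(self):
        rng = np.random.default_rng(2)
        wide = pd.DataFrame(
            {
                "tight": 20 + rng.normal(0, 0.2, size=20),
                "tight2": 21 + rng.normal(0, 0.3, size=20),
                "loose": 25 + rng.normal(0, 3.0, size=20),
            }
        )
        res = bestkeeper(wide)
        assert bool(res.summary.loc["tight", "reliable"])
        assert not bool(res.summary.loc["loose", "reliable"])

    def test_index_is_geometric_mean_of_complete_samples(self):
        rng = np.random.default_rng(3)
        wide = pd.DataFrame(rng.uniform(18, 30, size=(6, 3)), columns=["A", "B", "C"])
        wide.iloc[0, 1] = np.nan
        res = bestkeeper(wide)
        assert len(res.index) == 5
        np.testing.assert_allclose(res.index, stats.gmean(wide.dropna(), axis=1))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="3 complete samples"):
            bestkeeper(pd.DataFrame({"A": [20.0, 21.0], "B": [20.0, 21.0]}))


class TestComparativeDeltaCq:
    def test_constant_offset_pair_zero_sd(self):
        wide = pd.DataFrame({"A": [20.0, 21.0, 22.0], "B": [22.0, 23.0, 24.0],
                             "C": [20.0, 25.0, 19.0]})
        scores = comparative_delta_cq(wide)
        # SD(A-B) = 0 enters both A's and B's averages
        sd_ac = float((wide["A"] - wide["C"]).std(ddof=1))
        sd_bc = float((wide["B"] - wide["C"]).std(ddof=1))
        assert scores.scores["A"] == pytest.approx(sd_ac / 2)
        assert scores.scores["B"] == pytest.approx(sd_bc / 2)

    def test_three_gene_hand_oracle(self):
        """A=(20,21,22), B=(20,22,24), C=(20,20,20) => scores 1.0, 1.5, 1.5."""
        wide = pd.DataFrame(
            {"A": [20.0, 21.0, 22.0], "B": [20.0, 22.0, 24.0], "C": [20.0, 20.0, 20.0]}
        )
        scores = comparative_delta_cq(wide).scores
        assert scores["A"] == pytest.approx(1.0)
        assert scores["B"] == pytest.approx(1.5)
        assert scores["C"] == pytest.approx(1.5)
        assert comparative_delta_cq(wide).ranking[0] == "A"


@pytest.mark.parametrize("seed", [0, 7, 23])
def test_all_rankings_are_permutations_with_finite_scores(seed):
    rq = random_rq(seed, n=10, g=5, groups=["a"] * 5 + ["b"] * 5)
    wide = 25.0 - np.log2(rq.values)  # positive Cq-like scale
    for scores in (
        genorm(rq).scores(),
        normfinder(rq, rq.groups).scores(),
        bestkeeper(wide).scores(),
        comparative_delta_cq(wide),
    ):
        assert sorted(scores.ranking) == sorted(rq.genes)
        assert np.isfinite(scores.scores).all()
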