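"""Mixed-model ICC stability: REML engine, intervals, search, planning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from refstab.datamodel import ValidationError
from refstab.lmm import (
    IccResult,
    LmmSpec,
    MomentSet,
    _designs,
    _fit_variance_ratio,
    bonett_sample_size,
    classify_reliability,
    fit_combination,
    sample_size_table,
    search_combinations,
    variance_of_product,
)
from tests.conftest import make_rq


def simulate_latent(seed, n_per_group=(10, 10), sigma_b=1.0, sigma_e=(0.5, 0.5),
                    shifts=None, missing=0.0):
    """Direct latent-scale generator (log2 RQ) for LMM unit tests."""
    rng = np.random.default_rng(seed)
    genes = [f"RG{i + 1}" for i in range(len(sigma_e))]
    rows_groups, vals = [], []
    for gi, npg in enumerate(n_per_group):
        for _ in range(npg):
            b = rng.normal(0, sigma_b)
            y = [
                (shifts[gi][k] if shifts else 0.0) + b + rng.normal(0, sigma_e[k])
                for k in range(len(genes))
            ]
            vals.append(y)
            rows_groups.append(f"G{gi + 1}")
    arr = 2.0 ** np.array(vals)
    if missing > 0:
        mask = rng.random(arr.shape) < missing
        arr[mask] = np.nan
    return make_rq(arr, genes, groups=rows_groups)


class TestEngine:
    def test_matches_statsmodels_reml_and_ml(self):
        """Independent oracle: statsmodels MixedLM on unbalanced data."""
        smf = pytest.importorskip("statsmodels.formula.api")
        rq = simulate_latent(1, n_per_group=(8, 6, 10), sigma_e=(0.7, 0.7, 0.7))
        df = np.log2(rq.values).stack(future_stack=True).rename("y").reset_index()
        df.columns = ["sample", "gene", "y"]
        df["group"] = df["sample"].map(rq.groups)
        X_full, _, s = _designs(df)
        y = df["y"].to_numpy()

        fit = _fit_variance_ratio(y, X_full, s, reml=True)
        m = smf.mixedlm("y ~ C(gene)*C(group)", df, groups=df["sample"]).fit(reml=True)
        assert fit.sigma2_sample == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma2_error == pytest.approx(float(m.scale), rel=1e-3)

        fit_ml = _fit_variance_ratio(y, X_full, s, reml=False)
        m_ml = smf.mixedlm("y ~ C(gene)*C(group)", df, groups=df["sample"]).fit(reml=False)
        assert fit_ml.neg2ll == pytest.approx(-2.0 * float(m_ml.llf), abs=1e-4)

    def test_matches_statsmodels_with_missing_cells(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        rq = simulate_latent(2, n_per_group=(12, 12), sigma_e=(0.6, 0.6, 0.6), missing=0.15)
        df = np.log2(rq.values).stack(future_stack=True).rename("y").reset_index()
        df.columns = ["sample", "gene", "y"]
        df["group"] = df["sample"].map(rq.groups)
        df = df.dropna().reset_index(drop=True)
        X_full, _, s = _designs(df)
        fit = _fit_variance_ratio(df["y"].to_numpy(), X_full, s, reml=True)
        m = smf.mixedlm("y ~ C(gene)*C(group)", df, groups=df["sample"]).fit(reml=True)
        assert fit.sigma2_sample == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=5e-3, abs=1e-6)
        assert fit.sigma2_error == pytest.approx(float(m.scale), rel=5e-3)


class TestFitCombination:
    def test_perfect_agreement_gives_icc_one(self):
        rng = np.random.default_rng(0)
        y1 = rng.normal(0, 1, size=12)
        vals = 2.0 ** np.column_stack([y1, y1 + 1.5])  # constant log2 offset
        rq = make_rq(vals, ["A", "B"], groups=["g1"] * 6 + ["g2"] * 6)
        res = fit_combination(rq, None, ("A", "B"))
        assert res.sigma2_error == pytest.approx(0.0, abs=1e-6)
        assert res.icc == pytest.approx(1.0, abs=1e-6)

    def test_fband_anova_hand_oracle_single_group(self):
        """For one group the F interval must reproduce the classical
        two-way (samples x genes) ANOVA computed here from scratch."""
        rq = simulate_latent(5, n_per_group=(15,), sigma_e=(0.6, 0.6))
        res = fit_combination(rq, None, ("RG1", "RG2"), LmmSpec(ci_method="fband"))

        y = np.log2(rq.values[["RG1", "RG2"]].to_numpy())
        n, k = y.shape
        grand = y.mean()
        ms_s = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_e = (
            ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        F = ms_s / ms_e
        fl = F / stats.f.ppf(0.975, n - 1, (n - 1) * (k - 1))
        fu = F * stats.f.ppf(0.975, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        assert res.ci_lower == pytest.approx(max(lo, 0.0), abs=1e-9)
        assert res.ci_upper == pytest.approx(min(hi, 1.0), abs=1e-9)
        # balanced REML point estimate equals the ANOVA estimator
        assert res.icc == pytest.approx((F - 1) / (F + k - 1), abs=1e-6)

    def test_ci_contains_point_estimate(self):
        for seed in range(6):
            rq = simulate_latent(seed, n_per_group=(6, 6), sigma_b=0.8)
            res = fit_combination(rq, None, ("RG1", "RG2"))
            assert res.ci_lower <= res.icc <= res.ci_upper
            assert 0.0 <= res.ci_lower and res.ci_upper <= 1.0

    def test_bootstrap_used_for_missing_data(self):
        rq = simulate_latent(3, n_per_group=(10, 10), sigma_e=(0.5, 0.5, 0.5), missing=0.1)
        res = fit_combination(rq, None, ("RG1", "RG2", "RG3"),
                              LmmSpec(n_boot=200), seed=1)
        assert res.ci_method == "bootstrap"
        assert res.ci_lower <= res.icc <= res.ci_upper

    def test_balanced_fband_and_bootstrap_agree(self):
        """Interval-method cross-validation at n = 50, k = 2."""
        rq = simulate_latent(11, n_per_group=(50,), sigma_b=1.2, sigma_e=(0.6, 0.6))
        a = fit_combination(rq, None, ("RG1", "RG2"), LmmSpec(ci_method="fband"))
        b = fit_combination(rq, None, ("RG1", "RG2"),
                            LmmSpec(ci_method="bootstrap", n_boot=2000), seed=4)
        assert a.ci_lower == pytest.approx(b.ci_lower, abs=0.03)
        assert a.ci_upper == pytest.approx(b.ci_upper, abs=0.03)

    def test_lrt_detects_injected_group_shift(self):
        shifts = [[0.0, 0.0], [1.5, 0.0]]  # gene RG1 moves with treatment
        rq = simulate_latent(7, n_per_group=(12, 12), sigma_e=(0.3, 0.3), shifts=shifts)
        res = fit_combination(rq, None, ("RG1", "RG2"))
        assert res.lrt_p is not None and res.lrt_p <= 0.05
        assert res.systematic_effects is True

    def test_single_group_has_no_lrt(self):
        rq = simulate_latent(8, n_per_group=(10,))
        res = fit_combination(rq, None, ("RG1", "RG2"))
        assert res.lrt_p is None and res.systematic_effects is None

    def test_degenerate_constant_data(self):
        vals = np.full((8, 2), 4.0)
        rq = make_rq(vals, ["A", "B"])
        res = fit_combination(rq, None, ("A", "B"))
        assert "degenerate_fit_zero_variance" in res.flags

    def test_requires_two_genes(self):
        rq = simulate_latent(0)
        with pytest.raises(ValidationError, match="at least 2 genes"):
            fit_combination(rq, None, ("RG1",))


class TestSearch:
    def test_duplicate_pair_beats_noise_gene(self):
        rng = np.random.default_rng(21)
        base = rng.normal(0, 1.5, size=40)
        vals = 2.0 ** np.column_stack(
            [base + rng.normal(0, 0.05, 40),
             base + rng.normal(0, 0.05, 40),
             rng.normal(0, 1.5, size=40)]
        )
        rq = make_rq(vals, ["dup1", "dup2", "noise"],
                     groups=["a"] * 20 + ["b"] * 20)
        res = search_combinations(rq, rq.groups, max_k=3)
        assert set(res.selected.combination) == {"dup1", "dup2"}
        assert res.stop_reason == "lower_bound_no_increase"

    def test_pure_noise_still_selects_argmax_lower_bound(self):
        rng = np.random.default_rng(33)
        vals = 2.0 ** rng.normal(0, 1, size=(30, 4))
        rq = make_rq(vals, list("WXYZ"), groups=["a"] * 15 + ["b"] * 15)
        res = search_combinations(rq, rq.groups, max_k=3)
        best = max(res.results, key=lambda r: r.ci_lower)
        assert res.selected.ci_lower == best.ci_lower
        assert res.selected.icc <= 0.5  # genuinely unstable panel

    def test_selected_has_maximal_lower_bound(self, sim_rq):
        res = search_combinations(sim_rq, sim_rq.groups, max_k=3)
        assert res.selected.ci_lower == max(r.ci_lower for r in res.results)
        ranked = res.ranking()
        assert all(
            ranked[i].ci_lower >= ranked[i + 1].ci_lower for i in range(len(ranked) - 1)
        )


class TestClassifyReliability:
    @pytest.mark.parametrize(
        "icc, lo, hi, label",
        [
            (0.86, 0.65, 1.0, "moderate to good"),
            (0.95, 0.92, 0.99, "excellent"),
            (0.4, 0.1, 0.6, "poor"),
            (0.97, 0.80, 1.0, "good to excellent"),
        ],
    )
    def test_banding(self, icc, lo, hi, label):
        res = IccResult(("A", "B"), 1.0, 0.2, icc, lo, hi, None, None, "fband", 50, 1)
        assert classify_reliability(res) == label


class TestBonett:
    def test_published_planning_value(self):
        assert bonett_sample_size(0.86, 2, 0.1, 0.95) == 106

    def test_direct_formula_evaluation(self):
        # ceil(8 * 1.959964^2 * 0.04 * 6.76 / 0.24 + 1) evaluated by hand
        assert bonett_sample_size(0.8, 3, 0.2, 0.95) == 36

    def test_perfect_reliability_degenerates_to_one(self):
        assert bonett_sample_size(1.0, 2, 0.1) == 1

    def test_fewer_than_two_raters_rejected(self):
        with pytest.raises(ValidationError, match="2 raters"):
            bonett_sample_size(0.8, 1, 0.1)

    @given(
        rho=st.floats(0.5, 0.95),
        drho=st.floats(0.01, 0.04),
        k=st.integers(2, 6),
        w=st.floats(0.05, 0.5),
        dw=st.floats(0.01, 0.3),
    )
    def test_monotone_in_rho_and_width(self, rho, drho, k, w, dw):
        """Higher reliability or a looser precision target never needs more
        samples (rho restricted to the planning half where the (1-rho)
        (1+(k-1)rho) factor is decreasing)."""
        assert bonett_sample_size(rho + drho, k, w) <= bonett_sample_size(rho, k, w)
        assert bonett_sample_size(rho, k, w + dw) <= bonett_sample_size(rho, k, w)

    def test_table_contains_planning_cell_and_scales(self):
        tab = sample_size_table()
        cell = tab[(tab.rho == 0.86) & (tab.k == 2) & (tab.width == 0.1)]
        assert cell["n"].iloc[0] == 106
        # n - 1 ~ w^-2 (the +1 and the ceiling sit outside the scaling)
        wide = tab[(tab.rho == 0.86) & (tab.k == 2) & (tab.width == 0.2)]["n"].iloc[0]
        assert cell["n"].iloc[0] - 1 == pytest.approx(4 * (wide - 1), rel=0.05)
        by_rho = tab[(tab.k == 2) & (tab.width == 0.1)].sort_values("rho")["n"]
        assert (np.diff(by_rho) <= 0).all()


class TestVarianceOfProduct:
    def test_constants_have_zero_variance(self):
        assert variance_of_product(MomentSet(0.0, 0.0, 3.0, 2.0)) == 0.0

    def test_independent_direct_evaluation(self):
        m = MomentSet(var_x=0.04, var_y=0.09, mu_x=1.0, mu_y=2.0)
        assert variance_of_product(m) == pytest.approx(0.2536)

    def test_independent_matches_monte_carlo(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0.1, 0.2, size=1_000_000)
        y = rng.lognormal(0.4, 0.3, size=1_000_000)
        m = MomentSet(x.var(), y.var(), x.mean(), y.mean())
        assert variance_of_product(m) == pytest.approx((x * y).var(), rel=0.01)

    def test_dependent_matches_monte_carlo_on_correlated_lognormals(self):
        rng = np.random.default_rng(9)
        z = rng.multivariate_normal([0.0, 0.2], [[0.09, 0.05], [0.05, 0.16]], size=1_000_000)
        x, y = np.exp(z[:, 0]), np.exp(z[:, 1])
        m = MomentSet(
            var_x=x.var(), var_y=y.var(), mu_x=x.mean(), mu_y=y.mean(),
            cov_xy=np.cov(x, y)[0, 1], cov_x2y2=np.cov(x**2, y**2)[0, 1],
        )
        # exact moment identity: agreement is limited only by MC error
        assert variance_of_product(m, independent=False) == pytest.approx(
            (x * y).var(), rel=0.005
        )

    def test_dependent_requires_covariances(self):
        with pytest.raises(ValidationError, match="cov"):
            variance_of_product(MomentSet(1.0, 1.0, 0.0, 0.0), independent=False)
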