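"""NB GLM fitting, dispersion estimation, LRT calibration and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import statsmodels.api as sm

import trnapool as tp
from trnapool.de import (
    aggregate_families,
    bh_adjust,
    estimate_dispersion,
    fit_nb_glm,
    lrt,
    nb_loglik,
    run_de,
)
from conftest import make_count_matrix

X64 = np.r_[np.zeros(6), np.ones(4)]


class TestDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            y = rng.poisson(1000, 20)
            if estimate_dispersion(y, np.ones(20), np.r_[np.zeros(10), np.ones(10)]) <= 0.01:
                hits += 1
        assert hits >= 190  # >= 95% of trials

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(8)
        mu, alpha = 200.0, 0.5
        r = 1 / alpha
        estimates = [
            estimate_dispersion(
                rng.negative_binomial(r, r / (r + mu), 100),
                np.ones(100),
                np.r_[np.zeros(50), np.ones(50)],
            )
            for _ in range(200)
        ]
        assert 0.35 <= float(np.median(estimates)) <= 0.65

    def test_constant_counts_hit_lower_clamp(self):
        y = np.full(10, 50)
        assert estimate_dispersion(y, np.ones(10), X64) < 1e-6

    def test_all_zero_feature_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_dispersion(np.zeros(10), np.ones(10), X64)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            estimate_dispersion(np.array([1, 2]), np.ones(2), np.array([0, 1]))


class TestFit:
    def test_equal_group_means_give_zero_lfc(self):
        y = np.array([100, 110, 90, 100, 100, 100, 95, 105, 100, 100])
        # make the factor-weighted group means exactly equal
        s = np.ones(10)
        q0 = y[:6].mean()
        y2 = np.r_[y[:6], np.full(4, q0)]
        fit = fit_nb_glm(np.round(y2), s, X64, alpha=0.1)
        assert fit.log2_fold_change == pytest.approx(0.0, abs=1e-8)

    def test_halved_ki_means_give_lfc_minus_one(self):
        y = np.r_[np.full(6, 100.0), np.full(4, 50.0)]
        fit = fit_nb_glm(y, np.ones(10), X64, alpha=0.05)
        assert fit.log2_fold_change == pytest.approx(-1.0, abs=1e-8)

    def test_irls_reaches_closed_form_group_means(self):
        # equal size factors: the NB MLE group means are the plain group means
        rng = np.random.default_rng(9)
        y = rng.poisson(80, 10).astype(float)
        fit = fit_nb_glm(y, np.ones(10), X64, alpha=0.2)
        assert fit.converged
        expected_mu = np.where(X64 == 0, y[:6].mean(), y[6:].mean())
        assert np.allclose(fit.fitted_means, expected_mu, rtol=1e-8)

    def test_irls_poisson_limit_weighted_group_means(self):
        # alpha = 0 with unequal factors: MLE means are factor-weighted means
        rng = np.random.default_rng(19)
        y = rng.poisson(80, 10).astype(float)
        s = rng.uniform(0.5, 1.5, 10)
        fit = fit_nb_glm(y, s, X64, alpha=0.0)
        q = np.array([y[:6].sum() / s[:6].sum(), y[6:].sum() / s[6:].sum()])
        expected_mu = s * np.where(X64 == 0, q[0], q[1])
        assert np.allclose(fit.fitted_means, expected_mu, rtol=1e-8)

    def test_irls_improves_on_weighted_mean_start_when_overdispersed(self):
        # alpha > 0 with unequal factors: IRLS must not lose likelihood
        # relative to the factor-weighted group-mean starting point
        rng = np.random.default_rng(9)
        y = rng.poisson(80, 10).astype(float)
        s = rng.uniform(0.5, 1.5, 10)
        alpha = 0.2
        fit = fit_nb_glm(y, s, X64, alpha=alpha)
        q = np.array([y[:6].sum() / s[:6].sum(), y[6:].sum() / s[6:].sum()])
        start_mu = s * np.where(X64 == 0, q[0], q[1])
        assert fit.log_likelihood >= nb_loglik(y, start_mu, alpha) - 1e-10

    def test_poisson_limit_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(10)
        y = rng.poisson(30, 10).astype(float)
        s = rng.uniform(0.8, 1.2, 10)
        full = fit_nb_glm(y, s, X64, alpha=0.0)
        reduced = fit_nb_glm(y, s, None, alpha=0.0)
        X = sm.add_constant(X64)
        oracle_full = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(s)).fit()
        oracle_red = sm.GLM(y, np.ones((10, 1)), family=sm.families.Poisson(), offset=np.log(s)).fit()
        assert full.log_likelihood == pytest.approx(oracle_full.llf, abs=1e-6)
        assert reduced.log_likelihood == pytest.approx(oracle_red.llf, abs=1e-6)
        stat, _ = lrt(full, reduced)
        oracle_stat = 2 * (oracle_full.llf - oracle_red.llf)
        assert stat == pytest.approx(oracle_stat, abs=1e-5)

    def test_zero_ki_group_reported_at_boundary(self):
        y = np.r_[np.full(6, 500.0), np.zeros(4)]
        fit = fit_nb_glm(y, np.ones(10), X64, alpha=0.1)
        assert fit.boundary
        assert fit.log2_fold_change < -10


class TestLRT:
    def test_identical_group_means_stat_zero(self):
        y = np.full(10, 40.0)
        full = fit_nb_glm(y, np.ones(10), X64, alpha=0.1)
        reduced = fit_nb_glm(y, np.ones(10), None, alpha=0.1)
        stat, p = lrt(full, reduced)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_chi_square_reference_quantile(self):
        y = np.r_[np.full(6, 100.0), np.full(4, 70.0)]
        full = fit_nb_glm(y, np.ones(10), X64, alpha=0.0)
        reduced = fit_nb_glm(y, np.ones(10), None, alpha=0.0)
        stat, p = lrt(full, reduced)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(stat, 1))
        assert abs(chi2.sf(3.841, 1) - 0.05) < 1e-3  # the reference's 5% point

    def test_mismatched_alpha_rejected(self):
        y = np.full(10, 40.0)
        full = fit_nb_glm(y, np.ones(10), X64, alpha=0.1)
        reduced = fit_nb_glm(y, np.ones(10), None, alpha=0.2)
        with pytest.raises(ValueError, match="dispersion"):
            lrt(full, reduced)

    def test_likelihood_monotonicity_across_features(self, default_sim):
        ds = default_sim
        filt = tp.filter_low(ds.counts, ds.registry, 10)
        sf = tp.median_of_ratios_factors(filt, ds.registry.control_ids("both"))
        s = sf.factors.to_numpy()
        x = (filt.genotypes == "KI").to_numpy(float)
        for fid in filt.feature_ids[:60]:
            y = filt.counts.loc[fid].to_numpy(float)
            alpha = estimate_dispersion(y, s, x)
            full = fit_nb_glm(y, s, x, alpha)
            reduced = fit_nb_glm(y, s, None, alpha)
            assert full.log_likelihood >= reduced.log_likelihood - 1e-8


class TestBH:
    def test_hand_computed_triple(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, ps):
        # independent step-up computation: q_(k) = min_{j>=k} p_(j) * m / j
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), oracle)


class TestRunDE:
    def test_extreme_separation_is_significant(self, small_registry):
        rng = np.random.default_rng(11)
        counts = rng.poisson(200, size=(9, 10))
        counts[0, 6:] = 0  # KI columns all zero for one feature
        cm = make_count_matrix(
            counts,
            [g for g in small_registry.genes],
            [f"s{i}" for i in range(10)],
            ["WT"] * 6 + ["KI"] * 4,
        )
        sf = tp.sum_of_controls_factors(cm, small_registry, "both")
        res = run_de(cm, sf, small_registry, level="isodecoder")
        top = res.iloc[0]
        assert top["log2FoldChange"] < -5
        assert top["padj"] < 0.05

    def test_decoder_counts_conserve_reads_exactly(self, default_sim):
        ds = default_sim
        agg = aggregate_families(ds.counts, ds.registry)
        for fam in ds.registry.families:
            expected = ds.counts.counts.loc[list(fam.member_gene_ids)].sum(axis=0)
            assert (agg.counts.loc[fam.family_id] == expected).all()

    def test_sample_and_feature_order_invariance(self, small_sim):
        ds = small_sim
        filt = tp.filter_low(ds.counts, ds.registry, 10)
        sf = tp.median_of_ratios_factors(filt, ds.registry.control_ids("both"))
        res = run_de(filt, sf, ds.registry, level="isodecoder")

        rng = np.random.default_rng(12)
        feat_perm = rng.permutation(filt.feature_ids)
        samp_perm = list(rng.permutation(filt.sample_ids))
        shuffled = tp.CountMatrix(
            filt.counts.loc[feat_perm, samp_perm], filt.samples.loc[samp_perm]
        )
        sf2 = tp.SizeFactors(sf.factors.loc[samp_perm], sf.method, sf.control_set)
        res2 = run_de(shuffled, sf2, ds.registry, level="isodecoder")
        # identical up to floating-point summation order inside the
        # dispersion optimizer and IRLS (no structural order dependence)
        pd.testing.assert_frame_equal(
            res.sort_index(), res2.sort_index(), rtol=1e-4, atol=1e-6
        )

    def test_errors_recorded_not_raised(self, small_registry):
        counts = np.full((9, 10), 50)
        counts[0] = 0  # all-zero nuclear feature
        cm = make_count_matrix(
            counts, [g for g in small_registry.genes],
            [f"s{i}" for i in range(10)], ["WT"] * 6 + ["KI"] * 4,
        )
        sf = tp.sum_of_controls_factors(cm, small_registry, "both")
        res = run_de(cm, sf, small_registry, level="isodecoder")
        first = res.loc["tRNA-Ser-AGA-1-1"]
        assert "all-zero" in first["note"]
        assert np.isnan(first["pvalue"])
        assert res["pvalue"].notna().sum() == 5  # remaining nuclear features tested

    def test_controls_never_tested(self, small_sim):
        ds = small_sim
        filt = tp.filter_low(ds.counts, ds.registry, 10)
        sf = tp.median_of_ratios_factors(filt, ds.registry.control_ids("both"))
        res = run_de(filt, sf, ds.registry, level="decoder")
        assert not set(res.index) & set(ds.registry.control_ids("both"))
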