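import numpy as np
import pandas as pd
import pytest

from plasmodebench.containers import CountMatrix
from plasmodebench.de_engines import (
    _GRID,
    EngineConfig,
    _cr_apl_scalar,
    _mom_alpha,
    compare_tests,
    estimate_common_dispersion,
    estimate_genewise_dispersion,
    estimate_prior_df,
    fit_dispersion_trend,
    map_dispersion,
    moderate_tagwise_dispersion,
    observation_weights,
    run_engine,
    run_robust_engine,
    run_shrink_engine,
    shrink_lfc,
)
from plasmodebench.nb_core import fit_nb_glm, two_group_design
from plasmodebench.synthetic import SimConfig, default_config, generate_counts, generate_null_counts

from conftest import make_counts

D8 = two_group_design([0, 0, 0, 0, 1, 1, 1, 1])


def _nb_draw(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size).astype(float)


class TestGenewiseDispersion:
    def test_grid_search_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = _nb_draw(rng, 40.0, 0.3, 8)
            if y.sum() == 0:
                continue
            a_opt = estimate_genewise_dispersion(y, D8)
            a0 = float(_mom_alpha(y[None, :], np.zeros(8), D8.X[:, 1])[0])
            mu = fit_nb_glm(y, D8, alpha=a0).mu
            grid = np.exp(np.linspace(np.log(1e-8), np.log(10), 10_000))
            vals = [_cr_apl_scalar(y, D8, mu, a) for a in grid]
            a_grid = grid[int(np.argmax(vals))]
            # within grid resolution (log-spacing ~ 0.2%)
            assert np.log(a_opt) == pytest.approx(np.log(a_grid), abs=0.01)

    def test_poisson_data_gives_small_alpha(self):
        rng = np.random.default_rng(1)
        design = two_group_design(np.r_[np.zeros(50), np.ones(50)])
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            y = rng.poisson(500.0, 100).astype(float)
            if estimate_genewise_dispersion(y, design) < 0.01:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_alpha_recovery(self):
        rng = np.random.default_rng(2)
        design = two_group_design(np.r_[np.zeros(100), np.ones(100)])
        est = [
            estimate_genewise_dispersion(_nb_draw(rng, 200.0, 0.4, 200), design)
            for _ in range(50)
        ]
        assert np.mean(est) == pytest.approx(0.4, rel=0.15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_genewise_dispersion(np.zeros(8), D8)


class TestDispersionTrend:
    def test_self_consistency(self):
        means = np.linspace(1, 200, 100)
        genewise = 0.1 + 2.0 / means
        a0, a1 = fit_dispersion_trend(means, genewise)
        assert a0 == pytest.approx(0.1, rel=0.05)
        assert a1 == pytest.approx(2.0, rel=0.05)

    def test_constant_dispersion(self):
        means = np.linspace(5, 500, 80)
        a0, a1 = fit_dispersion_trend(means, np.full(80, 0.25))
        assert a0 == pytest.approx(0.25, rel=0.05)
        assert a1 == pytest.approx(0.0, abs=0.05)

    def test_outlier_excluded_on_second_pass(self):
        means = np.linspace(1, 200, 100)
        genewise = 0.1 + 2.0 / means
        clean = fit_dispersion_trend(means, genewise)
        dirty_gw = genewise.copy()
        dirty_gw[50] = 9.5  # massive outlier
        dirty = fit_dispersion_trend(means, dirty_gw)
        assert dirty[0] == pytest.approx(clean[0], rel=0.02)
        assert dirty[1] == pytest.approx(clean[1], rel=0.02)

    def test_fallback_to_median(self):
        with pytest.warns(UserWarning, match="flat median"):
            a0, a1 = fit_dispersion_trend(np.array([1.0, 2.0]), np.array([0.3, 0.4]))
        assert a1 == 0.0


class TestMapDispersion:
    def test_degenerate_prior_returns_trend(self):
        rng = np.random.default_rng(3)
        y = _nb_draw(rng, 50.0, 0.3, 8)
        final = map_dispersion(0.8, 0.2, 1e-10, y, D8)
        assert np.log(final) == pytest.approx(np.log(0.2), abs=0.01)

    def test_flat_prior_returns_genewise(self):
        rng = np.random.default_rng(4)
        y = _nb_draw(rng, 50.0, 0.3, 8)
        gw = estimate_genewise_dispersion(y, D8)
        final = map_dispersion(gw, 0.05, 1e6, y, D8)
        assert np.log(final) == pytest.approx(np.log(gw), abs=0.01)

    def test_final_between_genewise_and_trend(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = _nb_draw(rng, 60.0, 0.5, 8)
            if y.sum() == 0:
                continue
            gw = estimate_genewise_dispersion(y, D8)
            trend = 0.1
            final = map_dispersion(gw, trend, 0.5, y, D8)
            lo, hi = sorted([np.log(gw), np.log(trend)])
            assert lo - 1e-6 <= np.log(final) <= hi + 1e-6

    def test_nonpositive_trend_rejected(self):
        with pytest.raises(ValueError):
            map_dispersion(0.1, 0.0, 1.0, np.ones(8), D8)


class TestShrinkLFC:
    def test_zero_mle_stays_zero(self):
        final, _ = shrink_lfc(np.array([0.0]), np.array([0.5]), 1.0)
        assert final[0] == 0.0

    def test_ridge_closed_form(self):
        final, _ = shrink_lfc(np.array([2.0]), np.array([1.0]), 1.0)
        assert final[0] == pytest.approx(1.0)

    def test_flat_prior_limit(self):
        final, _ = shrink_lfc(np.array([1.7]), np.array([0.3]), 1e6)
        assert final[0] == pytest.approx(1.7, rel=1e-6)

    def test_infinite_se_passthrough(self):
        final, se = shrink_lfc(np.array([3.0, 1.0]), np.array([np.inf, 0.5]), 1.0)
        assert final[0] == 0.0
        assert np.isinf(se[0])

    def test_never_amplifies(self):
        rng = np.random.default_rng(6)
        mle = rng.normal(0, 2, 100)
        se = rng.uniform(0.1, 3, 100)
        final, _ = shrink_lfc(mle, se, 0.8)
        assert np.all(np.abs(final) <= np.abs(mle) + 1e-12)


@pytest.fixture(scope="module")
def shrink_null_cm():
    return generate_null_counts(default_config(n_transcripts=400, seed=8))


@pytest.fixture(scope="module")
def robust_null_cm():
    return generate_null_counts(default_config(n_transcripts=400, seed=21))


@pytest.fixture(scope="module")
def tagwise_cm():
    rng = np.random.default_rng(14)
    mus = rng.uniform(20, 200, 150)
    alphas = rng.uniform(0.05, 0.8, 150)
    mat = np.array([_nb_draw(rng, m, a, 8) for m, a in zip(mus, alphas)])
    return make_counts(mat.astype(int))


class TestShrinkEngine:

    def test_row_count_and_padj(self, shrink_null_cm):
        res = run_shrink_engine(shrink_null_cm)
        assert len(res) == shrink_null_cm.n_transcripts
        ok = ~res["pvalue"].isna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "pvalue"] - 1e-12).all()
        assert (res["called"] == (res["padj"] <= 0.05)).all()

    def test_column_permutation_invariance(self, shrink_null_cm):
        res1 = run_shrink_engine(shrink_null_cm)
        perm = ["A2", "A1", "A3", "A4", "B3", "B1", "B2", "B4"]
        cm2 = shrink_null_cm.subset_samples(perm)
        res2 = run_shrink_engine(cm2)
        assert np.allclose(res1["pvalue"], res2["pvalue"], atol=1e-8)
        assert np.allclose(res1["lfc_mle"], res2["lfc_mle"], atol=1e-8)

    def test_deterministic(self, shrink_null_cm):
        a = run_shrink_engine(shrink_null_cm)
        b = run_shrink_engine(shrink_null_cm)
        pd.testing.assert_frame_equal(a, b)

    def test_spiked_high_count_power(self):
        lfc = {f"tx{i:06d}": 2.0 if i % 2 else -2.0 for i in range(40)}
        cfg = SimConfig(n_transcripts=400, logmean_location=6.0, logmean_scale=0.5,
                        disp_a0=0.05, disp_a1=0.1, disp_lognorm_sd=0.0,
                        true_lfc_map=lfc, seed=10)
        cm = generate_counts(cfg)
        res = run_shrink_engine(cm)
        assert res["called"].iloc[:40].mean() > 0.9


class TestCommonDispersion:
    def test_poisson_small(self):
        rng = np.random.default_rng(11)
        cm = make_counts(rng.poisson(100, size=(300, 8)))
        assert estimate_common_dispersion(cm) < 0.01

    def test_recovery(self):
        rng = np.random.default_rng(12)
        cm = make_counts(_nb_draw(rng, 100.0, 0.2, (1000, 8)).astype(int))
        assert estimate_common_dispersion(cm) == pytest.approx(0.2, rel=0.10)

    def test_transcript_order_invariant(self):
        rng = np.random.default_rng(13)
        mat = _nb_draw(rng, 50.0, 0.3, (200, 8)).astype(int)
        a = estimate_common_dispersion(make_counts(mat))
        b = estimate_common_dispersion(make_counts(mat[::-1]))
        assert a == pytest.approx(b, rel=1e-9)


class TestTagwiseModeration:

    def test_zero_prior_df_is_tagwise_mle(self, tagwise_cm):
        from plasmodebench.de_engines import _argmax_parabolic, _cond_loglik_matrix, _cond_setup

        finals = moderate_tagwise_dispersion(tagwise_cm, 0.0)
        Yp, group = _cond_setup(tagwise_cm)
        mle = _argmax_parabolic(_cond_loglik_matrix(Yp, group))
        assert np.allclose(finals, mle)

    def test_infinite_prior_df_is_common(self, tagwise_cm):
        finals = moderate_tagwise_dispersion(tagwise_cm, 1e8)
        common = estimate_common_dispersion(tagwise_cm)
        assert np.all(np.abs(np.log(finals) - np.log(common)) < 1e-4)

    def test_finals_between_mle_and_common(self, tagwise_cm):
        mle = moderate_tagwise_dispersion(tagwise_cm, 0.0)
        common = estimate_common_dispersion(tagwise_cm)
        finals = moderate_tagwise_dispersion(tagwise_cm, 10.0)
        lo = np.minimum(np.log(mle), np.log(common)) - 0.05
        hi = np.maximum(np.log(mle), np.log(common)) + 0.05
        frac_inside = np.mean((np.log(finals) >= lo) & (np.log(finals) <= hi))
        assert frac_inside > 0.95

    def test_negative_prior_df_rejected(self, tagwise_cm):
        with pytest.raises(ValueError):
            moderate_tagwise_dispersion(tagwise_cm, -1.0)


class TestPriorDFEstimate:
    def _sim(self, spread_sd, seed):
        rng = np.random.default_rng(seed)
        mus = rng.uniform(50, 500, 400)
        alphas = 0.2 * np.exp(rng.normal(0, spread_sd, 400))
        mat = np.array([_nb_draw(rng, m, a, 8) for m, a in zip(mus, alphas)])
        return make_counts(mat.astype(int))

    def test_no_spread_hits_cap(self):
        rng = np.random.default_rng(15)
        cm = make_counts(_nb_draw(rng, 200.0, 0.2, (400, 8)).astype(int))
        assert estimate_prior_df(cm) == pytest.approx(1e6)

    def test_monotone_decreasing_in_spread(self):
        ests = [np.median([estimate_prior_df(self._sim(sd, seed))
                           for seed in (0, 1, 2)])
                for sd in (0.5, 1.0, 2.0)]
        assert ests[0] > ests[1] > ests[2]

    def test_library_scale_stability(self):
        cm = self._sim(1.0, 20)
        scaled = CountMatrix(cm.counts * 3, cm.groups)
        a, b = estimate_prior_df(cm), estimate_prior_df(scaled)
        assert np.log(b) == pytest.approx(np.log(a), abs=np.log(1.6))

    def test_too_few_transcripts_rejected(self):
        cm = make_counts(np.full((10, 8), 5))
        with pytest.raises(ValueError):
            estimate_prior_df(cm)


class TestObservationWeights:
    def test_zero_residual_full_weight(self):
        w = observation_weights([10.0], [10.0], 0.1)
        assert w[0] == 1.0

    def test_two_k_half_weight(self):
        k = 1.345
        mu, alpha = 25.0, 0.0
        y = mu + 2 * k * np.sqrt(mu)
        w = observation_weights([y], [mu], alpha, k=k)
        assert w[0] == pytest.approx(0.5)

    def test_monotone_nonincreasing(self):
        mu = np.full(50, 20.0)
        ys = np.linspace(20, 300, 50)
        w = observation_weights(ys, mu, 0.2)
        assert np.all(np.diff(w) <= 1e-12)
        assert np.all((w > 0) & (w <= 1))


class TestRobustEngine:

    def test_row_count_padj_called(self, robust_null_cm):
        res = run_robust_engine(robust_null_cm, EngineConfig(engine="robust", prior_df=10.0))
        assert len(res) == robust_null_cm.n_transcripts
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()
        assert (res["called"] == (res["padj"] <= 0.05)).all()

    def test_classic_robust_concordant_without_outliers(self, robust_null_cm):
        robust = run_robust_engine(robust_null_cm, EngineConfig(engine="robust", prior_df=10.0))
        classic = run_robust_engine(robust_null_cm, EngineConfig(engine="classic", prior_df=10.0))
        agreement = (robust["called"] == classic["called"]).mean()
        assert agreement > 0.95

    def test_outlier_dampened_by_weights(self):
        rng = np.random.default_rng(22)
        mat = rng.poisson(100, size=(200, 8))
        mat[0, 6] *= 50  # single-sample outlier on a null transcript
        cm = make_counts(mat)
        robust = run_robust_engine(cm, EngineConfig(engine="robust", prior_df=10.0))
        classic = run_robust_engine(cm, EngineConfig(engine="classic", prior_df=10.0))
        assert robust["pvalue"].iloc[0] > classic["pvalue"].iloc[0]

    def test_estimated_prior_df_attr(self, robust_null_cm):
        res = run_robust_engine(robust_null_cm, EngineConfig(engine="robust", prior_df="estimated"))
        assert res.attrs["prior_df"] > 0

    def test_run_engine_dispatch(self, robust_null_cm):
        res = run_engine(robust_null_cm, EngineConfig(engine="classic", prior_df=4.0))
        assert "padj" in res.columns
        with pytest.raises(ValueError):
            run_engine(robust_null_cm, EngineConfig(engine="nope"))


class TestCompareTests:
    def test_self_comparison_no_discordance(self):
        cm = generate_null_counts(default_config(n_transcripts=200, seed=23))
        table, _ = compare_tests(cm)
        assert (table["p_wald"] < table["p_wald"]).sum() == 0

    def test_high_count_asymptotic_agreement(self):
        lfc = {f"tx{i:06d}": (2.0 if i % 2 else -2.0) for i in range(40)}
        cfg = SimConfig(n_transcripts=400, logmean_location=8.0, logmean_scale=0.3,
                        disp_a0=0.02, disp_a1=0.0, disp_lognorm_sd=0.0,
                        true_lfc_map=lfc, seed=2)
        table, _ = compare_tests(generate_counts(cfg))
        ratio = np.abs(
            np.log10(np.maximum(table["p_wald"], 1e-300))
            - np.log10(np.maximum(table["p_lrt"], 1e-300))
        )
        assert np.median(ratio) < 0.1

    def test_stratified_summary_contract(self):
        from plasmodebench.count_prep import classify_abundance

        cm = generate_null_counts(default_config(n_transcripts=300, seed=24))
        classes = classify_abundance(cm)
        _, summary = compare_tests(cm, classes=classes)
        assert set(summary["stratum"]) == {"all", "low", "high"}
        assert summary["frac_wald_smaller"].between(0, 1).all()
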