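"""Posterior inference, HDI decisions, scores, and assay orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mprabayes.inference import (
    FitConfig,
    _borderline,
    classify,
    ess_mean,
    fit_assay,
    fit_variant,
    hdi,
    laplace_approximation,
    log_posterior,
    logpost_and_grad,
    refine_if_borderline,
    sample_posterior,
    screen_variant,
    significance_score,
    split_rhat,
    transcription_shift,
)
from mprabayes.nb import VariantData, VariantParameters, fit_variant_mle, loglik_and_grad
from mprabayes.priors import GammaPrior, PriorSet

from conftest import make_variant_data


class TestLogPosterior:
    def test_matches_naive_sum_of_likelihood_and_gamma_logpdfs(self, generic_priors):
        rng = np.random.default_rng(0)
        data = make_variant_data(rng, n_per_allele=3)
        params = VariantParameters(
            mu_dna=rng.gamma(5, 10, size=6), mu_allele=[0.8, 1.4],
            phi_dna=9.0, phi_allele=[7.0, 11.0],
        )
        x = params.to_vector()
        ll, _ = loglik_and_grad(x, data)
        pr = generic_priors
        naive_prior = (
            pr.mu_dna.logpdf(params.mu_dna).sum()
            + pr.mu_rna_ref.logpdf(params.mu_allele[0])
            + pr.mu_rna_alt.logpdf(params.mu_allele[1])
            + pr.phi_dna.logpdf(params.phi_dna)
            + pr.phi_rna.logpdf(params.phi_allele).sum()
            # Jacobian of theta = exp(x): sum of log-parameters
            + x.sum()
        )
        assert abs(log_posterior(params, data, pr) - (ll + naive_prior)) < 1e-8

    def test_flat_prior_differences_reduce_to_likelihood(self):
        rng = np.random.default_rng(1)
        data = make_variant_data(rng, n_per_allele=2)
        flat = GammaPrior(1.0, 1e-6)
        priors = PriorSet(flat, flat, flat, flat, flat)
        x1 = rng.normal(1.0, 0.3, size=data.n_params)
        x2 = rng.normal(1.0, 0.3, size=data.n_params)
        lp1, _ = logpost_and_grad(x1, data, priors)
        lp2, _ = logpost_and_grad(x2, data, priors)
        ll1, _ = loglik_and_grad(x1, data)
        ll2, _ = loglik_and_grad(x2, data)
        # with shape 1, rate ~ 0 the prior contributes ~ x.sum() (the Jacobian)
        assert abs((lp1 - lp2) - (ll1 - ll2) - (x1.sum() - x2.sum())) < 1e-3

    def test_degenerate_priors_dominate_the_posterior(self):
        rng = np.random.default_rng(2)
        data = make_variant_data(rng, n_per_allele=2)
        tight = lambda m: GammaPrior(1e8, 1e8 / m)   # mean m, sd ~ m * 1e-4
        priors = PriorSet(tight(50.0), tight(1.0), tight(1.0), tight(10.0), tight(10.0))
        x_mode = np.log(np.concatenate([np.full(4, 50.0), [1, 1, 10, 10, 10]]))
        lp_mode, _ = logpost_and_grad(x_mode, data, priors)
        for j in range(data.n_params):
            xp = x_mode.copy()
            xp[j] += 0.05
            lp, _ = logpost_and_grad(xp, data, priors)
            assert lp < lp_mode


class TestHdi:
    def test_uniform_integers(self):
        samples = np.arange(1.0, 101.0)
        lo, hi = hdi(samples, 0.95)
        assert hi - lo == 94.0
        assert lo == 1.0  # ties broken by lowest start

    def test_standard_normal_large_sample(self):
        draws = np.random.default_rng(3).standard_normal(100_000)
        lo, hi = hdi(draws, 0.95)
        assert abs(lo + 1.96) < 0.03
        assert abs(hi - 1.96) < 0.03

    def test_exponential_hdi_starts_at_mode(self):
        draws = np.random.default_rng(4).exponential(1.0, size=100_000)
        lo, hi = hdi(draws, 0.90)
        assert lo < 0.02           # mode of a monotone density
        assert abs(hi - 2.30) < 0.05

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50.0), 0.95)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        mass=st.floats(0.5, 0.99),
        loc=st.floats(-3.0, 3.0),
    )
    def test_hdi_is_narrowest_window_of_required_mass(self, seed, mass, loc):
        draws = np.random.default_rng(seed).normal(loc, 1.0, size=400)
        lo, hi = hdi(draws, mass)
        s = np.sort(draws)
        m = int(np.ceil(mass * len(s)))
        inside = ((draws >= lo) & (draws <= hi)).sum()
        assert inside >= m
        widths = s[m - 1 :] - s[: len(s) - m + 1]
        assert (hi - lo) <= widths.min() + 1e-12


class TestClassify:
    @pytest.mark.parametrize("interval,rope,expected", [
        ((0.1, 0.5), None, True),
        ((-0.2, 0.5), None, False),
        ((-0.5, -0.01), None, True),
        ((0.05, 0.5), (-0.1, 0.1), False),   # overlaps the ROPE
        ((0.05, 0.5), None, True),
        ((0.12, 0.5), (-0.1, 0.1), True),
    ])
    def test_hdi_and_rope_rules(self, interval, rope, expected):
        assert classify(interval, rope) is expected


def brute_force_score(draws, step=0.001):
    """Independent scan over every grid mass; mirrors the definition."""
    s = np.sort(draws)
    n = s.size
    for q in np.arange(step, 1.0, step):
        m = int(np.ceil(q * n))
        best, lo_best = np.inf, None
        for i in range(n - m + 1):
            w = s[i + m - 1] - s[i]
            if w < best:
                best, lo_best = w, i
        if s[lo_best] <= 0.0 <= s[lo_best + m - 1]:
            return 1.0 - q
    return 1.0 - (np.arange(step, 1.0, step))[-1]


class TestSignificanceScore:
    def test_symmetric_draws_score_near_one(self):
        # the empirical HDI at tiny masses jitters around the mode, so the
        # score of a perfectly null posterior lands high but not exactly at 1
        draws = np.random.default_rng(5).standard_normal(4000)
        assert significance_score(draws) > 0.8

    def test_one_sided_draws_hit_the_floor(self):
        draws = 0.5 + np.random.default_rng(6).random(2000)
        assert significance_score(draws) == pytest.approx(0.001)

    def test_matches_brute_force_grid_oracle(self):
        draws = np.random.default_rng(7).normal(1.0, 1.0, size=1500)
        assert significance_score(draws) == pytest.approx(brute_force_score(draws))

    def test_lower_score_for_stronger_shift(self):
        rng = np.random.default_rng(8)
        weak = significance_score(rng.normal(0.5, 1.0, size=4000))
        strong = significance_score(rng.normal(2.0, 1.0, size=4000))
        assert strong < weak


class TestTranscriptionShift:
    def test_identities(self):
        draws = np.exp(np.random.default_rng(9).normal(0, 1, size=(200, 9)))
        draws[:, 5] = draws[:, 4]                       # mu_alt = mu_ref
        assert np.allclose(transcription_shift(draws, 4), 0.0)
        draws[:, 5] = 2.0 * draws[:, 4]
        assert np.allclose(transcription_shift(draws, 4), np.log(2.0))

    def test_swapping_alleles_negates_ts(self):
        draws = np.exp(np.random.default_rng(10).normal(0, 1, size=(200, 9)))
        swapped = draws.copy()
        swapped[:, [4, 5]] = swapped[:, [5, 4]]
        np.testing.assert_allclose(
            transcription_shift(swapped, 4), -transcription_shift(draws, 4)
        )


class TestBorderlineRule:
    @pytest.mark.parametrize("interval,expected", [
        ((0.001, 0.4), True),     # 0.001 < 0.1 * 0.399
        ((0.2, 0.6), False),
        ((-0.4, -0.001), True),
        ((-0.2, 0.5), False),
    ])
    def test_edge_near_zero_triggers(self, interval, expected):
        assert _borderline(interval, 0.10) is expected


class TestSampler:
    def test_diagnostics_match_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(11)
        x = rng.standard_normal((4, 500))
        assert split_rhat(x) == pytest.approx(float(az.rhat(x, method="split")), rel=1e-9)
        assert ess_mean(x) == pytest.approx(float(az.ess(x, method="mean")), rel=0.05)
        y = np.cumsum(rng.standard_normal((4, 500)), axis=1) * 0.05 + x
        assert split_rhat(y) == pytest.approx(float(az.rhat(y, method="split")), rel=1e-9)

    def test_seed_stability_of_ts_mean(self, generic_priors):
        rng = np.random.default_rng(12)
        data = make_variant_data(rng, n_per_allele=10, mu_alt=1.5)
        means, ses = [], []
        for seed in (1, 2):
            post = sample_posterior(data, generic_priors, FitConfig(seed=seed),
                                    rng=np.random.default_rng(seed))
            means.append(post.ts_draws.mean())
            ses.append(post.ts_draws.std() / np.sqrt(post.ess_min))
        assert abs(means[0] - means[1]) < 3.0 * np.hypot(*ses)

    def test_agrees_with_emcee_on_a_small_variant(self, generic_priors):
        # independent gradient-free sampler as an oracle for the HMC draws
        emcee = pytest.importorskip("emcee")
        rng = np.random.default_rng(13)
        data = make_variant_data(rng, n_per_allele=2, mu_alt=2.0)
        post = sample_posterior(data, generic_priors, FitConfig(seed=0, sampling=2000),
                                rng=np.random.default_rng(0))

        def logp(x):
            lp, _ = logpost_and_grad(x, data, generic_priors)
            return lp

        ndim = data.n_params
        lap = laplace_approximation(data, generic_priors)
        walkers = 4 * ndim
        p0 = lap.x_map + 0.1 * rng.standard_normal((walkers, ndim))
        sampler = emcee.EnsembleSampler(walkers, ndim, logp)
        sampler.run_mcmc(p0, 4000, progress=False)
        chain = sampler.get_chain(discard=1500, flat=True)
        tau = float(np.max(sampler.get_autocorr_time(discard=1500, quiet=True)))
        n_eff_emcee = len(chain) / max(tau, 1.0)
        ts_emcee = chain[:, ndim - 4] - chain[:, ndim - 5]
        ts_mine = post.ts_draws
        se = ts_mine.std() * np.sqrt(1 / post.ess_min + 1 / n_eff_emcee)
        assert abs(ts_mine.mean() - ts_emcee.mean()) < 4 * se
        assert abs(ts_mine.std() / ts_emcee.std() - 1.0) < 0.2

    def test_prior_dominates_limit(self):
        # near-degenerate mu_allele priors at 1 force |ts| ~ 0 whatever the data
        tight = GammaPrior(1e6, 1e6)
        priors = PriorSet(GammaPrior(5, 0.1), tight, tight,
                          GammaPrior(10, 1), GammaPrior(10, 1))
        rng = np.random.default_rng(14)
        for rep in range(4):
            data = make_variant_data(rng, n_per_allele=5, mu_alt=3.0)
            post = sample_posterior(data, priors, FitConfig(seed=rep),
                                    rng=np.random.default_rng(rep))
            assert abs(post.ts_draws.mean()) < 0.05

    def test_data_dominates_limit(self, generic_priors):
        broad = GammaPrior(0.1, 0.01)
        priors = PriorSet(GammaPrior(5, 0.1), broad, broad,
                          GammaPrior(10, 1), GammaPrior(10, 1))
        rng = np.random.default_rng(15)
        data = make_variant_data(rng, n_per_allele=100, mu_alt=2.0)
        mle = fit_variant_mle(data, seed=0)
        post = sample_posterior(data, priors, FitConfig(seed=0),
                                rng=np.random.default_rng(0))
        assert abs(post.ts_draws.mean() - mle.ts) < 0.05


class TestScreen:
    def test_strongly_functional_variant_is_kept(self, generic_priors):
        kept = 0
        for rep in range(10):
            rng = np.random.default_rng(400 + rep)
            data = make_variant_data(rng, n_per_allele=30, mu_alt=np.exp(1.5))
            kept += screen_variant(data, generic_priors).keep
        assert kept == 10

    def test_null_variant_is_usually_skipped(self, generic_priors):
        kept = 0
        for rep in range(12):
            rng = np.random.default_rng(500 + rep)
            data = make_variant_data(rng, n_per_allele=30, mu_alt=1.0)
            kept += screen_variant(data, generic_priors).keep
        assert kept <= 4

    def test_disabling_screen_sends_all_to_mcmc(self, generic_priors):
        rng = np.random.default_rng(16)
        data = make_variant_data(rng, n_per_allele=3)
        fit = fit_variant(data, generic_priors, FitConfig(seed=0, screen=False), seed=0)
        assert fit.stage in ("mcmc", "mcmc_refined")


class TestRefinement:
    def test_borderline_fit_is_refined(self, generic_priors):
        # a weak shift whose HDI edge lands near zero
        for rep in range(8):
            rng = np.random.default_rng(600 + rep)
            data = make_variant_data(rng, n_per_allele=10, mu_alt=1.25)
            fit = fit_variant(data, generic_priors, FitConfig(seed=rep), seed=rep)
            if fit.stage == "mcmc_refined":
                assert len(fit.ts_draws) >= 4 * 2000
                return
        pytest.skip("no borderline fit arose in 8 attempts")

    def test_refinement_grows_draws_and_reduces_endpoint_noise(self, generic_priors):
        rng = np.random.default_rng(17)
        data = make_variant_data(rng, n_per_allele=10, mu_alt=1.3)
        lows_base, lows_ref = [], []
        for seed in range(6):
            base = sample_posterior(data, generic_priors, FitConfig(seed=seed),
                                    rng=np.random.default_rng(seed))
            refined = sample_posterior(data, generic_priors, FitConfig(seed=seed),
                                       rng=np.random.default_rng(100 + seed),
                                       sampling=500 * 4)
            lows_base.append(hdi(base.ts_draws, 0.95)[0])
            lows_ref.append(hdi(refined.ts_draws, 0.95)[0])
        assert np.std(lows_ref) < np.std(lows_base)


class TestAntisymmetry:
    def test_relabeling_alleles_negates_posterior_ts(self, generic_priors):
        rng = np.random.default_rng(18)
        data = make_variant_data(rng, n_per_allele=8, mu_alt=1.8)
        swapped = VariantData(
            data.variant_id, data.dna, data.rna, ~data.alt, data.d_dna, data.d_rna
        )
        post = sample_posterior(data, generic_priors, FitConfig(seed=0),
                                rng=np.random.default_rng(0))
        post_sw = sample_posterior(swapped, generic_priors, FitConfig(seed=0),
                                   rng=np.random.default_rng(0))
        se = post.ts_draws.std() * np.sqrt(1 / post.ess_min + 1 / post_sw.ess_min)
        assert abs(post.ts_draws.mean() + post_sw.ts_draws.mean()) < 4 * se


class TestFitAssay:
    def test_serial_and_parallel_runs_are_identical(self, small_assay):
        table, _, depths = small_assay
        sub = table.frame[table.frame["variant_id"].isin(table.variant_ids[:20])]
        from mprabayes.io import CountTable

        small = CountTable(sub.reset_index(drop=True), table.sample_types)
        r1 = fit_assay(small, cfg=FitConfig(seed=5))
        r2 = fit_assay(small, cfg=FitConfig(seed=5, n_workers=2))
        pd.testing.assert_frame_equal(r1.results, r2.results)

    def test_per_variant_failures_are_isolated(self, small_assay, generic_priors, monkeypatch):
        table, _, depths = small_assay
        sub = table.frame[table.frame["variant_id"].isin(table.variant_ids[:8])]
        from mprabayes.io import CountTable
        from mprabayes import inference

        small = CountTable(sub.reset_index(drop=True), table.sample_types)
        bad = small.variant_ids[3]
        orig = inference.fit_variant

        def sabotaged(data, priors, cfg, seed=None, mle=None):
            if data.variant_id == bad:
                raise RuntimeError("corrupt data")
            return orig(data, priors, cfg, seed=seed, mle=mle)

        monkeypatch.setattr(inference, "fit_variant", sabotaged)
        out = fit_assay(small, priors=generic_priors, cfg=FitConfig(seed=1))
        assert set(out.failures) == {bad}
        assert len(out.results) == 7
        assert out.n_failed == 1

    def test_grouped_prior_mode_runs_end_to_end(self, small_assay):
        from mprabayes.io import AnnotationTable

        table, truth, depths = small_assay
        vids = table.variant_ids
        labels = pd.DataFrame(
            {"class": ["a" if i < len(vids) // 2 else "b" for i in range(len(vids))]},
            index=pd.Index(vids, name="variant_id"),
        )
        out = fit_assay(table, priors="grouped", cfg=FitConfig(seed=3),
                        annotations=AnnotationTable(labels, "categorical"))
        assert set(out.priors) == {"a", "b"}
        assert len(out.results) == len(vids)
        assert out.priors["a"].provenance.startswith("grouped:a")

    def test_results_table_schema(self, small_assay, generic_priors):
        table, _, depths = small_assay
        sub = table.frame[table.frame["variant_id"].isin(table.variant_ids[:6])]
        from mprabayes.io import CountTable

        small = CountTable(sub.reset_index(drop=True), table.sample_types)
        out = fit_assay(small, priors=generic_priors, cfg=FitConfig(seed=2))
        assert list(out.results.columns) == [
            "variant_id", "ts_mean", "hdi_lower", "hdi_upper", "score",
            "functional_call", "stage", "rhat_max", "ess_min",
        ]
        assert out.results["score"].between(0, 1).all()
        assert (out.results["hdi_lower"] < out.results["hdi_upper"]).all()
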