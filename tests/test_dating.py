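import numpy as np
import pytest
from scipy import stats

from tipchron.dating import (
    ClockPriors,
    McmcConfig,
    TipDate,
    TipDateSpec,
    _TruncatedGamma,
    fit_prior,
    hpd_interval,
    individual_dating,
    joint_dating,
    log_posterior,
    mcmc_run,
    summarize,
)
from tipchron.phylo import Alignment, SubstModel, empirical_base_freqs
from tipchron.simulate import SimConfig, simulate_dataset

from .oracles import hpd_bruteforce


def _recovery_problem(seed=3, n_undated=2, chain=30_000, seq_length=4_000):
    rng = np.random.default_rng(seed)
    ages = np.sort(np.concatenate([[0.0], rng.uniform(0, 2.5e5, 7)]))
    cfg = SimConfig(n_tips=8, tip_ages=ages, pop_size=1e5, rate=3e-8,
                    seq_length=seq_length, seed=seed + 1)
    aln, truth = simulate_dataset(cfg)
    oldest = sorted(truth.true_tip_ages, key=truth.true_tip_ages.get)[-n_undated:]
    tips = {
        l: (
            TipDate(status="estimated", lower=5e4, upper=8e5)
            if l in oldest
            else TipDate(status="fixed", point_age=a)
        )
        for l, a in truth.true_tip_ages.items()
    }
    spec = TipDateSpec(tips, reference_age=0.0)
    model = SubstModel(kappa=20.0, base_freqs=empirical_base_freqs(aln),
                       alpha=0.5, rate=2e-8)
    mc = McmcConfig(chain_length=chain, sample_every=50, seed=seed + 2,
                    n_replicates=1)
    return aln, truth, spec, model, mc, oldest


class TestTruncatedGamma:
    @pytest.mark.parametrize("shape,scale", [(1.0, 2e5), (2.5, 7e4)])
    def test_matches_scipy_inside_support(self, shape, scale):
        lo, hi = 5e4, 8e5
        tg = _TruncatedGamma(shape, scale, lo, hi)
        z = stats.gamma.cdf(hi, a=shape, scale=scale) - stats.gamma.cdf(
            lo, a=shape, scale=scale
        )
        for x in (5e4, 1e5, 4e5, 8e5):
            expected = stats.gamma.logpdf(x, a=shape, scale=scale) - np.log(z)
            assert tg.logpdf(x) == pytest.approx(expected, abs=1e-10)

    def test_outside_support_is_minus_inf(self):
        tg = _TruncatedGamma(1.0, 2e5, 5e4, 8e5)
        assert tg.logpdf(4.9e4) == -np.inf
        assert tg.logpdf(8.1e5) == -np.inf


class TestLogPosterior:
    def test_rate_outside_prior_is_minus_inf(self, two_tip_tree, model):
        spec = TipDateSpec({"a": TipDate("fixed", 0.0), "b": TipDate("fixed", 0.0)})
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        priors = ClockPriors()
        ok = log_posterior((two_tip_tree, 1e-8, 1e5), aln, spec, priors, model)
        assert np.isfinite(ok)
        bad = log_posterior((two_tip_tree, 1e-7, 1e5), aln, spec, priors, model)
        assert bad == -np.inf

    def test_tip_age_truncation_boundary(self, model):
        from tipchron.tree import TimeTree

        spec = TipDateSpec(
            {"a": TipDate("fixed", 0.0),
             "b": TipDate("estimated", lower=5e4, upper=8e5)}
        )
        priors = ClockPriors()
        for age, finite in [(5e4 + 1, True), (8e5 - 1, True), (4e4, False)]:
            tree = TimeTree(["a", "b"], [2, 2, -1],
                            [[-1, -1], [-1, -1], [0, 1]], [0.0, age, 9e5])
            lp = log_posterior((tree, 1e-8, 1e5), None, spec, priors, model)
            assert np.isfinite(lp) == finite


class TestHpdInterval:
    def test_consecutive_integers_tie_toward_lower_start(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert (lo, hi) == (1, 95)

    def test_exponential_upper_bound(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(1.0, 100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(0.0, abs=1e-3)
        assert hi == pytest.approx(-np.log(0.05), rel=0.02)

    def test_matches_bruteforce_windows(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 1.0, 500)
        assert hpd_interval(x, 0.9) == hpd_bruteforce(x, 0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([], 0.95)


class TestFitPrior:
    def test_flat_samples_give_flat_density(self):
        rng = np.random.default_rng(3)
        a, b = 2e5, 6e5
        spec = fit_prior(rng.uniform(a, b, 5_000), a, b)
        mid = np.linspace(a + 0.1 * (b - a), b - 0.1 * (b - a), 50)
        dens = np.array([np.exp(spec.logpdf(x)) for x in mid])
        np.testing.assert_allclose(dens, 1.0 / (b - a), rtol=0.10)

    def test_point_mass_integrates_to_one(self):
        spec = fit_prior(np.full(200, 3e5), 5e4, 8e5)
        assert np.trapezoid(spec.density, spec.grid) == pytest.approx(1.0, abs=1e-3)
        assert spec.logpdf(3e5) > spec.logpdf(5e5)

    def test_truncated_exponential_moment_preserved(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(2e5, 20_000)
        x = x[(x >= 5e4) & (x <= 8e5)]
        spec = fit_prior(x, 5e4, 8e5)
        assert spec.mean == pytest.approx(x.mean(), rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fit_prior(np.linspace(1e5, 2e5, 50), 5e4, 8e5)


class TestSummarize:
    def test_constant_column_warns_low_ess(self):
        aln, truth, spec, model, mc, oldest = _recovery_problem(chain=2_000,
                                                                seq_length=500)
        tr = mcmc_run(aln, truth.true_tree, spec, None, model, mc)
        tr.data["const"] = 1.0
        with pytest.warns(UserWarning, match="low ESS"):
            s = summarize(tr, targets=["const"])
        assert s["median"].iloc[0] == 1.0

    def test_iid_draws_have_ess_near_n(self):
        import pandas as pd

        from tipchron.dating import Trace

        rng = np.random.default_rng(5)
        n = 4_000
        df = pd.DataFrame({"step": np.arange(1, n + 1), "x": rng.normal(size=n)})
        tr = Trace(data=df, acceptance={}, seed=0)
        s = summarize(tr, targets=["x"])
        assert s["ess"].iloc[0] == pytest.approx(n, rel=0.2)


class TestMcmc:
    def test_fixed_seed_is_bit_reproducible(self):
        aln, truth, spec, model, mc, _ = _recovery_problem(chain=2_000,
                                                           seq_length=500)
        t1 = mcmc_run(aln, truth.true_tree, spec, None, model, mc)
        t2 = mcmc_run(aln, truth.true_tree, spec, None, model, mc)
        assert t1.data.equals(t2.data)

    def test_start_state_outside_prior_reports_term(self):
        aln, truth, spec, model, mc, _ = _recovery_problem(chain=1_000,
                                                           seq_length=500)
        bad = ClockPriors(rate_lower=4e-10, rate_upper=8e-8,
                          pop_lower=1.0, pop_upper=1e6)
        # tip prior bounds that exclude the start tree's tip age
        for l in spec.estimated_labels():
            spec.tips[l] = TipDate("estimated", lower=7.9e5, upper=8e5)
        with pytest.raises(ValueError, match="tip-age"):
            mcmc_run(aln, truth.true_tree, spec, bad, model, mc)

    def test_acceptance_rates_within_tuning_targets(self):
        aln, truth, spec, model, mc, _ = _recovery_problem(chain=20_000,
                                                           seq_length=2_000)
        tr = mcmc_run(aln, truth.true_tree, spec, None, model, mc)
        for move, rate in tr.acceptance.items():
            assert 0.05 < rate < 0.8, f"{move} acceptance {rate:.2f}"

    def test_prior_only_marginal_matches_truncated_gamma(self):
        spec = TipDateSpec(
            {"x": TipDate("estimated", prior_shape=1.0, prior_scale=2e5,
                          lower=5e4, upper=8e5),
             "y": TipDate("fixed", point_age=0.0)}
        )
        mc = McmcConfig(chain_length=120_000, sample_every=50, seed=7,
                        n_replicates=1, burnin_fraction=1 / 6)
        tr = mcmc_run(None, None, spec, None, None, mc, prior_only=True)
        x = tr["age_x"]
        lo, hi, s = 5e4, 8e5, 2e5

        def cdf(v):
            return (1 - np.exp(-(np.asarray(v) - lo) / s)) / (
                1 - np.exp(-(hi - lo) / s)
            )

        assert stats.kstest(x, cdf).pvalue > 0.01

    def test_estimated_tip_age_recovers_truth(self):
        aln, truth, spec, model, mc, oldest = _recovery_problem(
            seed=11, n_undated=1, chain=40_000
        )
        tr = mcmc_run(aln, truth.true_tree, spec, None, model, mc)
        label = oldest[0]
        med = np.median(tr[f"age_{label}"])
        assert med == pytest.approx(truth.true_tip_ages[label], rel=0.25)


class TestProcedures:
    def test_joint_reports_bp_medians_and_hpds(self):
        aln, truth, spec, model, mc, oldest = _recovery_problem(chain=10_000)
        res = joint_dating(aln, truth.true_tree, spec, None, model, mc)
        assert set(f"age_{l}" for l in oldest) <= set(res.summary["parameter"])
        assert len(res.traces) == mc.n_replicates

    def test_individual_matches_joint_with_single_undated_tip(self):
        # with one undated tip the ID stage-3 run re-uses its own stage-1
        # posterior as prior, so the two procedures should agree
        aln, truth, spec, model, mc, oldest = _recovery_problem(
            seed=23, n_undated=1, chain=40_000
        )
        label = oldest[0]
        jt = joint_dating(aln, truth.true_tree, spec, None, model, mc)
        idv = individual_dating(aln, truth.true_tree, spec, None, model, mc)
        mj = jt.summary.set_index("parameter").loc[f"age_{label}", "median"]
        mi = idv.summary.set_index("parameter").loc[f"age_{label}", "median"]
        sd = np.std(np.concatenate([t[f"age_{label}"] for t in jt.traces]))
        assert abs(mj - mi) < max(0.5 * sd, 0.05 * mj)

    def test_id_hpds_no_wider_than_prior_support(self):
        aln, truth, spec, model, mc, oldest = _recovery_problem(
            seed=29, n_undated=2, chain=15_000
        )
        res = individual_dating(aln, truth.true_tree, spec, None, model, mc)
        s = res.summary.set_index("parameter")
        for l in oldest:
            lo, hi = spec.rel_bounds(l)
            assert s.loc[f"age_{l}", "hpd95_high"] - s.loc[f"age_{l}", "hpd95_low"] \
                <= hi - lo

    def test_trace_steps_strictly_increasing(self):
        aln, truth, spec, model, mc, _ = _recovery_problem(chain=2_000,
                                                           seq_length=500)
        tr = mcmc_run(aln, truth.true_tree, spec, None, model, mc)
        assert np.all(np.diff(tr["step"]) > 0)
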