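import itertools

import numpy as np
import pytest
from scipy import stats

from snpburden.core_types import StudyData
from snpburden.likelihood import (RiskSetIndex, cond_logistic_loglik,
                                  linear_predictor)
from snpburden.prior_model import snp_prior_probs
from snpburden.sampler import (GibbsSampler, McmcConfig, initial_state,
                               run_mcmc)

from conftest import null_state, random_study, simple_prior


def _enumerate_w_posterior(data, prior, state):
    """Brute-force posterior over all weight configurations with every other
    parameter held fixed (the independent oracle for the W updates)."""
    rs = RiskSetIndex.from_study(data)
    nsg = data.snps_per_gene
    log_prior = {}
    for g, n in enumerate(nsg):
        p = snp_prior_probs(int(n), prior.nbar, prior.c, prior.phi_minus,
                            prior.phi_plus, scaling=prior.scaling)
        log_prior[g] = {-1: np.log(p[0]), 0: np.log(p[1]), 1: np.log(p[2])}
    configs = list(itertools.product((-1, 0, 1), repeat=data.n_snps))
    logw = np.empty(len(configs))
    for k, cfg in enumerate(configs):
        st = state.copy()
        st.w = np.array(cfg, dtype=np.int8)
        ll = cond_logistic_loglik(linear_predictor(st, data), rs)
        lp = sum(log_prior[int(data.snp_gene[s])][cfg[s]]
                 for s in range(data.n_snps))
        logw[k] = ll + lp
    post = np.exp(logw - logw.max())
    post /= post.sum()
    marg = np.zeros((data.n_snps, 3))
    for k, cfg in enumerate(configs):
        for s, d in enumerate(cfg):
            marg[s, d + 1] += post[k]
    return marg  # columns: d = -1, 0, +1


class TestUpdateW:
    def test_zero_phi_keeps_all_weights_zero(self):
        rng = np.random.default_rng(0)
        data = random_study(rng, n_sets=8)
        prior = simple_prior(phi=0.0)
        sampler = GibbsSampler(data, prior, McmcConfig(seed=1))
        for _ in range(20):
            sampler.update_w()
        assert (sampler.state.w == 0).all()

    def test_case_only_snp_driven_to_inclusion_as_beta_grows(self):
        # a SNP carried only by cases: Pr(W=+1 | rest) increases toward 1
        # with the gene coefficient, evaluated from the exact conditional
        y = np.array([1, 0] * 20)
        geno = np.zeros((40, 1), dtype=np.int8)
        geno[y == 1, 0] = 1
        data = StudyData(y=y, x=np.zeros((40, 0)), genotypes=geno,
                         snp_gene=[0], riskset=np.repeat(np.arange(20), 2),
                         offset=np.zeros(40))
        prior = simple_prior(n_genes=1, nbar=1.0)
        probs = []
        for beta in (0.0, 1.0, 4.0):
            st = null_state(1, 1)
            st.beta = np.array([beta])
            marg = _enumerate_w_posterior(data, prior, st)
            probs.append(marg[0, 2])
        assert probs[0] < probs[1] < probs[2]
        assert probs[2] > 0.99

    def test_symmetric_data_gives_symmetric_conditional(self):
        # identical genotype in case and control within every set: the
        # likelihood cannot distinguish +1 from -1
        rng = np.random.default_rng(4)
        geno_half = rng.binomial(2, 0.4, size=(10, 2)).astype(np.int8)
        geno = np.repeat(geno_half, 2, axis=0)
        y = np.array([1, 0] * 10)
        data = StudyData(y=y, x=np.zeros((20, 0)), genotypes=geno,
                         snp_gene=[0, 0], riskset=np.repeat(np.arange(10), 2),
                         offset=np.zeros(20))
        prior = simple_prior(n_genes=1, nbar=2.0)
        marg = _enumerate_w_posterior(data, prior, null_state(2, 1))
        np.testing.assert_allclose(marg[:, 0], marg[:, 2], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_w_gibbs_matches_enumeration(self, seed):
        # conditional-scan Gibbs (beta etc. fixed) against brute force over
        # all 3^n weight configurations
        rng = np.random.default_rng(200 + seed)
        data = random_study(rng, n_sets=20, n_genes=2, snps_per_gene=(2, 2))
        prior = simple_prior(nbar=2.0)
        st = null_state(data.n_snps, data.n_genes)
        st.beta = np.array([0.3, -0.2])
        expected = _enumerate_w_posterior(data, prior, st)
        sampler = GibbsSampler(data, prior, McmcConfig(seed=seed), state=st)
        n_scans = 4000
        counts = np.zeros((data.n_snps, 3))
        for _ in range(n_scans):
            sampler.update_w()
            for s in range(data.n_snps):
                counts[s, sampler.state.w[s] + 1] += 1
        freq = counts / n_scans
        # conservative MC-SE: assume effective sample size n/10 for the
        # autocorrelated Gibbs scan
        ess = n_scans / 10
        se = np.sqrt(expected * (1 - expected) / ess)
        assert (np.abs(freq - expected) < 3 * se + 0.01).all()


class TestUpdateBetaB:
    def test_prior_recovery_on_zero_information_data(self):
        # all genotypes zero: the likelihood is flat in beta, so the chain
        # must reproduce the joint prior.  Marginally pi_0 is Student-t with
        # 2 df (a N(0, V) scale mixture with V ~ IG(1, 1)), sigma2 and tau2
        # keep their IG priors, and beta adds the correlated and independent
        # normal components.  Heavily thinned draws pooled over seeds give
        # near-independent samples for the KS tests.
        rng = np.random.default_rng(9)
        data = random_study(rng, n_sets=10, n_genes=3, snps_per_gene=(1, 1, 1))
        data.genotypes[:] = 0
        prior = simple_prior(n_genes=3, nbar=1.0)
        h = prior.hyper
        pi, beta, s2, t2 = [], [], [], []
        for seed in range(5):
            chain = run_mcmc(data, prior,
                             McmcConfig(n_burnin=2000, n_keep=250, thin=60,
                                        seed=seed))
            pi.append(chain.pi[:, 0])
            beta.append(chain.beta[:, 0])
            s2.append(chain.sigma2)
            t2.append(chain.tau2)
        pi, beta = np.concatenate(pi), np.concatenate(beta)
        s2, t2 = np.concatenate(s2), np.concatenate(t2)
        assert stats.kstest(pi, lambda x: stats.t.cdf(x, 2)).pvalue > 0.01
        assert stats.kstest(
            s2, lambda x: stats.invgamma.cdf(x, h.df_e, scale=h.e)
        ).pvalue > 0.01
        assert stats.kstest(
            t2, lambda x: stats.invgamma.cdf(x, h.df_b, scale=h.b)
        ).pvalue > 0.01
        # beta against forward prior simulation (two-sample KS)
        ref_rng = np.random.default_rng(123)
        n_ref = 100_000
        vpi = h.p / ref_rng.gamma(1.0, 1.0, n_ref)
        s2r = h.e / ref_rng.gamma(h.df_e, 1.0, n_ref)
        t2r = h.b / ref_rng.gamma(h.df_b, 1.0, n_ref)
        beta_ref = (np.sqrt(vpi) * ref_rng.standard_normal(n_ref)
                    + np.sqrt(t2r) * ref_rng.standard_normal(n_ref)
                    + np.sqrt(s2r) * ref_rng.standard_normal(n_ref))
        assert stats.ks_2samp(beta, beta_ref).pvalue > 0.01

    def test_zero_proposal_scale_warns_and_leaves_state(self):
        rng = np.random.default_rng(2)
        data = random_study(rng)
        prior = simple_prior()
        with pytest.warns(UserWarning):
            cfg = McmcConfig(scale_beta=0.0, scale_b=0.0, seed=0)
        sampler = GibbsSampler(data, prior, cfg)
        before = sampler.state.beta.copy()
        with pytest.warns(UserWarning):
            sampler.update_beta_b()
        np.testing.assert_array_equal(sampler.state.beta, before)

    def test_adaptation_reaches_sensible_acceptance(self):
        rng = np.random.default_rng(3)
        data = random_study(rng, n_sets=40, n_cov=1)
        prior = simple_prior()
        cfg = McmcConfig(n_burnin=400, n_keep=600, seed=7)
        chain = run_mcmc(data, prior, cfg)
        acc = chain.meta["acceptance"]
        assert 0.1 < acc["beta_b"] < 0.6
        assert 0.1 < acc["alpha"] < 0.6


class TestUpdatePi:
    def test_intercept_only_diffuse_limit_is_least_squares(self):
        # with V_pi huge and sigma2=1, the conjugate draw centers on
        # mean(beta - b)
        rng = np.random.default_rng(11)
        data = random_study(rng, n_sets=6, n_genes=3, snps_per_gene=(1, 1, 1))
        prior = simple_prior(n_genes=3, nbar=1.0)
        st = null_state(3, 3)
        st.beta = np.array([0.5, 1.0, 1.5])
        st.sigma2 = 1.0
        st.vpi = 1e12
        draws = []
        sampler = GibbsSampler(data, prior, McmcConfig(seed=3), state=st)
        for _ in range(4000):
            sampler.state.vpi = 1e12
            sampler.state.sigma2 = 1.0
            sampler.update_pi()
            draws.append(sampler.state.pi[0])
        mean = np.mean(draws)
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert mean == pytest.approx(1.0, abs=5 * se + 1e-3)

    def test_zero_residuals_give_symmetric_zero_mean(self):
        rng = np.random.default_rng(12)
        data = random_study(rng, n_sets=6, n_genes=3, snps_per_gene=(1, 1, 1))
        prior = simple_prior(n_genes=3, nbar=1.0)
        st = null_state(3, 3)     # beta - b identically zero
        sampler = GibbsSampler(data, prior, McmcConfig(seed=4), state=st)
        draws = []
        for _ in range(3000):
            sampler.state.beta = np.zeros(3)
            sampler.state.b = np.zeros(3)
            sampler.update_pi()
            draws.append(sampler.state.pi[0])
        assert np.mean(draws) == pytest.approx(0.0, abs=0.05)

    def test_mh_mode_targets_same_distribution(self):
        rng = np.random.default_rng(13)
        data = random_study(rng, n_sets=6, n_genes=3, snps_per_gene=(1, 1, 1))
        prior = simple_prior(n_genes=3, nbar=1.0)
        st = null_state(3, 3)
        st.beta = np.array([0.4, -0.1, 0.6])
        draws = {}
        for mode in ("gibbs", "mh"):
            cfg = McmcConfig(seed=5, pi_update=mode, scale_pi=0.8)
            sampler = GibbsSampler(data, prior, cfg, state=st.copy())
            sampler._adapting = False
            out = []
            for _ in range(6000):
                sampler.state.beta = st.beta.copy()
                sampler.state.b = np.zeros(3)
                sampler.state.sigma2 = 0.25
                sampler.state.vpi = 1.0
                sampler.update_pi()
                out.append(sampler.state.pi[0])
            draws[mode] = np.array(out)
        p = stats.ks_2samp(draws["gibbs"][::5], draws["mh"][::20]).pvalue
        assert p > 0.01


class TestUpdateVariances:
    def test_zero_residual_ig_moments(self):
        # with e = 0 the sigma2 conditional is IG(df_e + N_G/2, E); the
        # sample mean over 1e5 draws must match E/(df_e + N_G/2 - 1) to 1%
        rng = np.random.default_rng(21)
        data = random_study(rng, n_sets=4, n_genes=3, snps_per_gene=(1, 1, 1))
        prior = simple_prior(n_genes=3, nbar=1.0)
        sampler = GibbsSampler(data, prior, McmcConfig(seed=8),
                               state=null_state(3, 3))
        s2 = np.empty(100_000)
        t2 = np.empty(100_000)
        for i in range(100_000):
            sampler.state.beta = np.zeros(3)
            sampler.state.b = np.zeros(3)
            sampler.state.pi = np.zeros(1)
            sampler.update_variances()
            s2[i] = sampler.state.sigma2
            t2[i] = sampler.state.tau2
        h = prior.hyper
        assert s2.mean() == pytest.approx(h.e / (h.df_e + 1.5 - 1), rel=0.01)
        # b = 0: tau2 posterior is the prior with updated shape only
        assert t2.mean() == pytest.approx(h.b / (h.df_b + 1.5 - 1), rel=0.01)
        assert (s2 > 0).all() and (t2 > 0).all()


class TestUpdateAlpha:
    def test_within_set_constant_covariate_is_unidentified_but_stable(self):
        rng = np.random.default_rng(31)
        data = random_study(rng, n_sets=10, set_size=2, n_cov=1)
        # covariate constant within each risk set
        vals = rng.standard_normal(10)
        data.x[:, 0] = vals[data.riskset]
        prior = simple_prior()
        chain = run_mcmc(data, prior, McmcConfig(n_burnin=50, n_keep=200,
                                                 seed=9))
        assert np.isfinite(chain.alpha).all()

    def test_posterior_mode_near_discordant_pair_mle(self):
        # 1:1 sets, binary covariate, no genetic effect: the conditional MLE
        # is log(n10/n01) over discordant pairs
        rng = np.random.default_rng(32)
        n_sets = 300
        x = rng.binomial(1, 0.5, size=2 * n_sets).astype(float)
        riskset = np.repeat(np.arange(n_sets), 2)
        # generate outcomes from a true log-OR of 0.8
        y = np.zeros(2 * n_sets, dtype=np.int8)
        for r in range(n_sets):
            i, j = 2 * r, 2 * r + 1
            p = np.exp(0.8 * x[[i, j]])
            y[[i, j][rng.choice(2, p=p / p.sum())]] = 1
        data = StudyData(y=y, x=x[:, None], genotypes=np.zeros((2 * n_sets, 2),
                                                               dtype=np.int8),
                         snp_gene=[0, 0], riskset=riskset,
                         offset=np.zeros(2 * n_sets))
        n10 = n01 = 0
        for r in range(n_sets):
            i, j = 2 * r, 2 * r + 1
            case = i if y[i] else j
            ctrl = j if y[i] else i
            if x[case] == 1 and x[ctrl] == 0:
                n10 += 1
            elif x[case] == 0 and x[ctrl] == 1:
                n01 += 1
        mle = np.log(n10 / n01)
        prior = simple_prior(n_genes=1, nbar=2.0)
        data.snp_gene = np.array([0, 0])
        chain = run_mcmc(data, prior, McmcConfig(n_burnin=300, n_keep=1500,
                                                 seed=10))
        post_mean = chain.alpha.mean()
        post_sd = chain.alpha.std(ddof=1)
        assert post_mean == pytest.approx(mle, abs=3.5 * post_sd)


class TestModelII:
    def _null_data(self, rng, n_genes=2):
        data = random_study(rng, n_sets=15, n_genes=n_genes,
                            snps_per_gene=(2,) * n_genes)
        return data

    def test_strongly_negative_prior_mean_keeps_beta_at_zero(self):
        rng = np.random.default_rng(41)
        data = self._null_data(rng)
        data.genotypes[:] = 0
        prior = simple_prior(nbar=2.0)
        cfg = McmcConfig(variant="modelII", seed=11)
        sampler = GibbsSampler(data, prior, cfg)
        sampler.state.pi = np.array([-3.0])
        sampler.state.sigma2 = 0.25
        at_zero = 0
        for _ in range(400):
            sampler.update_beta_model2()
            at_zero += (sampler.state.beta == 0).all()
        assert at_zero / 400 >= 0.95

    def test_zero_beta_contributes_nothing_to_eta(self):
        rng = np.random.default_rng(42)
        data = self._null_data(rng)
        prior = simple_prior(nbar=2.0)
        cfg = McmcConfig(variant="modelII", seed=12)
        sampler = GibbsSampler(data, prior, cfg)
        sampler.state.w[:] = 1
        sampler._refresh_caches()
        np.testing.assert_allclose(sampler.eta, sampler.base)

    def test_model2_chain_runs_and_keeps_beta_nonnegative(self):
        rng = np.random.default_rng(43)
        data = self._null_data(rng)
        prior = simple_prior(nbar=2.0)
        chain = run_mcmc(data, prior, McmcConfig(variant="modelII",
                                                 n_burnin=100, n_keep=300,
                                                 seed=13))
        assert (chain.beta >= 0).all()
        assert chain.meta["variant"] == "modelII"


class TestRunMcmc:
    def test_same_seed_gives_bit_identical_chains(self):
        rng = np.random.default_rng(51)
        data = random_study(rng, n_sets=12, n_cov=1)
        prior = simple_prior()
        cfg = McmcConfig(n_burnin=30, n_keep=60, seed=99)
        c1 = run_mcmc(data, prior, cfg)
        c2 = run_mcmc(data, prior, cfg)
        for name in ("w", "beta", "b", "pi", "alpha", "sigma2", "tau2"):
            np.testing.assert_array_equal(getattr(c1, name),
                                          getattr(c2, name))

    def test_chain_length_matches_config(self):
        rng = np.random.default_rng(52)
        data = random_study(rng, n_sets=6)
        prior = simple_prior()
        chain = run_mcmc(data, prior, McmcConfig(n_burnin=20, n_keep=50,
                                                 seed=1))
        assert chain.n_scans == 50
        assert chain.meta["n_burnin"] == 20

    def test_nonfinite_initial_loglik_raises(self):
        rng = np.random.default_rng(53)
        data = random_study(rng, n_sets=6)
        data.offset[0] = np.inf
        prior = simple_prior()
        with pytest.raises(FloatingPointError):
            GibbsSampler(data, prior, McmcConfig(seed=1))

    def test_dispersed_starts_agree_on_gene_inclusion(self):
        # two chains from different starting points reach the same gene
        # posterior inclusion probabilities
        rng = np.random.default_rng(54)
        data = random_study(rng, n_sets=60, n_genes=3,
                            snps_per_gene=(2, 3, 2), set_size=2)
        prior = simple_prior(n_genes=3, nbar=7 / 3)
        cfg = McmcConfig(n_burnin=500, n_keep=2500, seed=15)
        probs = []
        for start_w in (0, 1):
            st = initial_state(data, prior)
            if start_w:
                st.w[:] = 1
                st.beta += 1.0
            sampler = GibbsSampler(data, prior, cfg, state=st)
            chain = sampler.run()
            included = chain.w != 0
            gene_in = np.zeros((chain.n_scans, 3), dtype=bool)
            np.logical_or.at(gene_in.T, data.snp_gene, included.T)
            probs.append(gene_in.mean(axis=0))
        assert (np.abs(probs[0] - probs[1]) < 0.1).all()

    def test_incremental_loglik_cache_consistency(self):
        # after many mixed updates the cached eta / loglik equal a fresh
        # recomputation from the state
        rng = np.random.default_rng(55)
        data = random_study(rng, n_sets=15, n_cov=1)
        prior = simple_prior()
        sampler = GibbsSampler(data, prior, McmcConfig(seed=16))
        for _ in range(30):
            sampler.step()
        eta_cached = sampler.eta.copy()
        ll_cached = sampler.cur_ll
        sampler._refresh_caches()
        np.testing.assert_allclose(eta_cached, sampler.eta, atol=1e-10)
        assert ll_cached == pytest.approx(sampler.cur_ll, abs=1e-10)
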