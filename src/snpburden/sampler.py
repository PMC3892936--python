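"""MCMC fitting of the hierarchical SNP-set burden model.

One scan performs, in order:

1. ``update_W`` — each SNP weight is redrawn from its exact three-way full
   conditional Pr(W_gs = d) ∝ prior_d · L(W_gs = d), using incremental
   likelihood updates that touch only risk sets containing a carrier;
2. ``update_beta_b`` — a joint Metropolis-Hastings move of the gene
   coefficient vector beta and the correlated random effects b (multivariate
   normal random walk, the b proposal correlated through the similarity
   matrix A);
3. ``update_pi`` — the second-level coefficients; the level-2 model is
   linear-Gaussian so the exact conjugate Gibbs draw is used by default
   (a random-walk MH fallback is available);
4. ``update_variances`` — conjugate inverse-gamma Gibbs draws for sigma2,
   tau2 and V_pi;
5. ``update_alpha`` — random-walk MH for the fixed-covariate coefficients
   under a flat prior.

Under ``variant="modelII"`` step 2 is replaced by per-gene birth/death +
positive random-walk moves against the point-mass-at-zero plus
truncated-normal prior, and pi / sigma2 are updated by MH since the
point mass breaks conjugacy; the correlated effect b plays no role there.

Proposal scales adapt during burn-in only (Robbins-Monro toward an
acceptance rate of 0.3) and are frozen afterwards to preserve detailed
balance.  All randomness flows through a single seeded generator, so chains
are bit-reproducible.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .core_types import ChainSamples, ModelState, PriorSpec, StudyData
from .likelihood import RiskSetIndex, burden_matrix, gene_coefficients
from .prior_model import prior_prob_table

__all__ = [
    "McmcConfig",
    "GibbsSampler",
    "run_mcmc",
    "update_W",
    "update_beta_b",
    "update_pi",
    "update_variances",
    "update_alpha",
    "update_beta_modelII",
    "initial_state",
]

logger = logging.getLogger(__name__)

_WEIGHTS = (-1, 0, 1)


@dataclass
class McmcConfig:
    """Chain length, seed, proposal scales and variant selection."""

    n_burnin: int = 500
    n_keep: int = 1000
    thin: int = 1
    seed: int = 0
    scale_beta: float = 0.1
    scale_b: float = 0.1
    scale_pi: float = 0.3
    scale_alpha: float = 0.1
    adapt: bool = True
    target_accept: float = 0.3
    variant: str = "modelI"
    pi_update: str = "gibbs"

    def __post_init__(self):
        if self.n_keep < 1 or self.thin < 1 or self.n_burnin < 0:
            raise ValueError("need n_keep, thin >= 1 and n_burnin >= 0")
        for name in ("scale_beta", "scale_b", "scale_pi", "scale_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
            if getattr(self, name) == 0:
                warnings.warn(f"{name} = 0: that block will never move",
                              stacklevel=2)
        if self.variant not in ("modelI", "modelII"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.pi_update not in ("gibbs", "mh"):
            raise ValueError(f"unknown pi_update {self.pi_update!r}")


def _draw_inv_gamma(rng, shape: float, scale: float, size=None):
    """Inverse-gamma draw(s) in shape/scale form (mean scale/(shape-1))."""
    return scale / rng.gamma(shape, 1.0, size=size)


def initial_state(data: StudyData, prior: PriorSpec,
                  variant: str = "modelI") -> ModelState:
    """Null start: W = 0, pi = 0, beta at its prior mean Z'pi = 0, b = 0,
    alpha from one Newton step of the conditional logistic fit,
    sigma2 = tau2 = 0.25."""
    n_g = prior.n_genes
    p = data.x.shape[1]
    alpha = np.zeros(p)
    if p:
        alpha = _newton_step_alpha(data)
    beta0 = np.zeros(n_g)
    return ModelState(
        w=np.zeros(data.n_snps, dtype=np.int8),
        beta=beta0, b=np.zeros(n_g),
        pi=np.zeros(prior.z.shape[1]), alpha=alpha,
        sigma2=0.25, tau2=0.25, vpi=1.0,
    )


def _newton_step_alpha(data: StudyData) -> np.ndarray:
    """One Newton-Raphson step of the conditional logistic score at alpha=0."""
    rs = RiskSetIndex.from_study(data)
    x = data.x[rs.order]
    eta = data.offset[rs.order]
    bounds = np.r_[rs.starts, len(rs.order)]
    p_dim = x.shape[1]
    grad = np.zeros(p_dim)
    hess = np.zeros((p_dim, p_dim))
    for r in range(rs.n_sets):
        lo, hi = bounds[r], bounds[r + 1]
        w = np.exp(eta[lo:hi] - eta[lo:hi].max())
        w /= w.sum()
        xbar = w @ x[lo:hi]
        grad += x[rs.case_pos[r]] - xbar
        hess += (x[lo:hi] * w[:, None]).T @ x[lo:hi] - np.outer(xbar, xbar)
    try:
        return np.linalg.solve(hess, grad)
    except np.linalg.LinAlgError:
        return np.zeros(p_dim)


class GibbsSampler:
    """Holds data, prior, caches and proposal scales; exposes per-block
    updates plus :meth:`run`.

    Internally subjects are reordered so that risk sets are contiguous; the
    linear predictor ``eta`` and per-set log-sum-exp values are maintained
    incrementally across weight toggles.
    """

    def __init__(self, data: StudyData, prior: PriorSpec, cfg: McmcConfig,
                 state: ModelState | None = None,
                 rng: np.random.Generator | None = None):
        if prior.n_genes != data.n_genes:
            raise ValueError("prior Z rows must match the study's gene count")
        self.data = data
        self.prior = prior
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.rs = RiskSetIndex.from_study(data)

        order = self.rs.order
        self.S = data.genotypes[order].astype(np.float64)
        self.X = data.x[order]
        self.base_off = data.offset[order].astype(float)
        self.starts = self.rs.starts
        self.case_pos = self.rs.case_pos
        self.snp_gene = np.asarray(data.snp_gene)
        self.n_genes = data.n_genes
        self.n_snps = data.n_snps
        self.n_sets = self.rs.n_sets

        probs = prior_prob_table(prior, data.snps_per_gene)
        with np.errstate(divide="ignore"):
            self.log_prior_w = np.log(probs)  # (n_genes, 3) for d=-1,0,+1

        # similarity matrix pieces
        self.chol_a = np.linalg.cholesky(prior.a)
        self.a_inv = np.linalg.inv(prior.a)

        # per-SNP workspace: members of risk sets containing a carrier
        bounds = np.r_[self.starts, len(order)]
        set_of = np.repeat(np.arange(self.n_sets), np.diff(bounds))
        self._mem_idx, self._mem_off, self._aff_sets, self._s_mem = [], [], [], []
        self._case_dot = np.zeros(self.n_snps)
        for s in range(self.n_snps):
            carriers = np.flatnonzero(self.S[:, s])
            aff = np.unique(set_of[carriers])
            if aff.size == 0:
                self._aff_sets.append(aff)
                self._mem_idx.append(np.empty(0, dtype=np.intp))
                self._mem_off.append(np.empty(0, dtype=np.intp))
                self._s_mem.append(np.empty(0))
                continue
            sizes = bounds[aff + 1] - bounds[aff]
            off = np.r_[0, np.cumsum(sizes)[:-1]]
            mem = np.concatenate([np.arange(bounds[r], bounds[r + 1]) for r in aff])
            self._aff_sets.append(aff)
            self._mem_idx.append(mem.astype(np.intp))
            self._mem_off.append(off.astype(np.intp))
            self._s_mem.append(self.S[mem, s])
            self._case_dot[s] = self.S[self.case_pos, s].sum()

        self.state = (state.copy() if state is not None
                      else initial_state(data, prior, cfg.variant))
        # adaptive proposal scales (log domain)
        self.scales = {"beta_b": (cfg.scale_beta, cfg.scale_b),
                       "pi": cfg.scale_pi, "alpha": cfg.scale_alpha,
                       "beta2": cfg.scale_beta}
        self.accept_counts = {k: [0, 0] for k in ("beta_b", "pi", "alpha", "beta2")}
        self._adapting = False
        self._adapt_t = 0
        self._refresh_caches()
        if not np.isfinite(self.cur_ll):
            raise FloatingPointError(
                f"non-finite log-likelihood at initialization; state={self.state}")

    # -- cache maintenance -------------------------------------------------
    def _refresh_caches(self) -> None:
        st = self.state
        self.G = burden_matrix(st.w, self.S, self.snp_gene, self.n_genes)
        self.base = self.base_off + (self.X @ st.alpha if self.X.shape[1] else 0.0)
        coef = gene_coefficients(st, self.cfg.variant)
        self.eta = self.base + self.G @ coef
        self.lse = np.logaddexp.reduceat(self.eta, self.starts)
        self.cur_ll = float(self.eta[self.case_pos].sum() - self.lse.sum())

    def _ll_of_eta(self, eta: np.ndarray) -> tuple[float, np.ndarray]:
        lse = np.logaddexp.reduceat(eta, self.starts)
        return float(eta[self.case_pos].sum() - lse.sum()), lse

    # -- W update ----------------------------------------------------------
    def update_w(self) -> None:
        st = self.state
        coef = gene_coefficients(st, self.cfg.variant)
        logp_w = self.log_prior_w
        rng = self.rng
        for s in rng.permutation(self.n_snps):
            g = self.snp_gene[s]
            w_old = int(st.w[s])
            mem = self._mem_idx[s]
            if mem.size == 0:
                # no carriers: likelihood flat, sample from the prior
                lp = logp_w[g].copy()
            else:
                off = self._mem_off[s]
                sv = self._s_mem[s]
                eta_mem = self.eta[mem]
                l_aff = self.lse[self._aff_sets[s]]
                l_aff_sum = l_aff.sum()
                lp = np.empty(3)
                cand = {}
                for k, d in enumerate(_WEIGHTS):
                    if d == w_old:
                        lp[k] = logp_w[g, k]
                        continue
                    delta = coef[g] * (d - w_old)
                    new_eta = eta_mem + delta * sv
                    new_l = np.logaddexp.reduceat(new_eta, off)
                    lp[k] = (logp_w[g, k] + delta * self._case_dot[s]
                             - (new_l.sum() - l_aff_sum))
                    cand[d] = (new_eta, new_l)
            lp -= lp.max()
            p = np.exp(lp)
            p /= p.sum()
            u = rng.random()
            k_new = 0 if u < p[0] else (1 if u < p[0] + p[1] else 2)
            d_new = _WEIGHTS[k_new]
            if d_new == w_old:
                continue
            st.w[s] = d_new
            if mem.size:
                new_eta, new_l = cand[d_new]
                self.eta[mem] = new_eta
                self.lse[self._aff_sets[s]] = new_l
                self.G[mem, g] += (d_new - w_old) * self._s_mem[s]
        self.cur_ll = float(self.eta[self.case_pos].sum() - self.lse.sum())

    # -- beta block (Model I): MH for beta, exact Gibbs for b ---------------
    def _log_prior_beta(self, beta) -> float:
        st = self.state
        e = beta - (self.prior.z @ st.pi + st.b)
        return float(-0.5 * (e @ e) / st.sigma2)

    def update_beta_b(self) -> None:
        """Random-walk MH on the beta vector against the conditional
        logistic likelihood plus its N(Z'pi + b, sigma2) prior, followed by
        the exact Gaussian draw of b (which enters the likelihood only
        through beta, so its full conditional is conjugate:
        precision A^-1/tau2 + I/sigma2, mean matching beta - Z'pi)."""
        st = self.state
        s_beta, _ = self.scales["beta_b"]
        if s_beta == 0:
            warnings.warn("beta proposal scale is 0; state unchanged",
                          stacklevel=2)
            return
        beta_p = st.beta + s_beta * self.rng.standard_normal(self.n_genes)
        eta_p = self.base + self.G @ np.exp(beta_p)
        ll_p, lse_p = self._ll_of_eta(eta_p)
        log_r = (ll_p + self._log_prior_beta(beta_p)
                 - self.cur_ll - self._log_prior_beta(st.beta))
        acc = min(1.0, np.exp(min(log_r, 0.0)))
        if self.rng.random() < acc:
            st.beta = beta_p
            self.eta, self.lse, self.cur_ll = eta_p, lse_p, ll_p
            self.accept_counts["beta_b"][0] += 1
        self.accept_counts["beta_b"][1] += 1
        self._adapt("beta_b", acc)
        # conjugate Gibbs draw of the correlated random effect
        prec = self.a_inv / st.tau2 + np.eye(self.n_genes) / st.sigma2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, (st.beta - self.prior.z @ st.pi) / st.sigma2)
        noise = np.linalg.solve(chol.T, self.rng.standard_normal(self.n_genes))
        st.b = mean + noise

    # -- Model II beta moves ------------------------------------------------
    def update_beta_model2(self) -> None:
        """Per-gene birth/death + positive random-walk MH under the
        point-mass-at-zero plus truncated-normal prior."""
        st = self.state
        s = max(self.scales["beta2"], 1e-12)
        sigma = np.sqrt(st.sigma2)
        mu = self.prior.z @ st.pi
        from scipy.stats import norm
        acc_sum, n_prop = 0.0, 0
        for g in range(self.n_genes):
            bg = st.beta[g]
            col = self.G[:, g]
            if bg == 0.0:
                # birth: propose from half-normal(s)
                z = abs(self.rng.standard_normal()) * s
                eta_p = self.eta + z * col
                ll_p, lse_p = self._ll_of_eta(eta_p)
                log_num = (ll_p + norm.logpdf(z, mu[g], sigma)
                           + np.log(0.5))          # death proposed w.p. 0.5
                log_den = (self.cur_ll + norm.logcdf(-mu[g] / sigma)
                           + norm.logpdf(z, 0, s) + np.log(2.0))
                log_r = log_num - log_den
                new_val = z
            else:
                if self.rng.random() < 0.5:
                    # death: propose beta_g = 0
                    eta_p = self.eta - bg * col
                    ll_p, lse_p = self._ll_of_eta(eta_p)
                    log_num = (ll_p + norm.logcdf(-mu[g] / sigma)
                               + norm.logpdf(bg, 0, s) + np.log(2.0))
                    log_den = (self.cur_ll + norm.logpdf(bg, mu[g], sigma)
                               + np.log(0.5))
                    log_r = log_num - log_den
                    new_val = 0.0
                else:
                    z = bg + s * self.rng.standard_normal()
                    if z < 0:      # outside the support: auto-reject
                        n_prop += 1
                        self.accept_counts["beta2"][1] += 1
                        continue
                    eta_p = self.eta + (z - bg) * col
                    ll_p, lse_p = self._ll_of_eta(eta_p)
                    log_r = (ll_p + norm.logpdf(z, mu[g], sigma)
                             - self.cur_ll - norm.logpdf(bg, mu[g], sigma))
                    new_val = z
            acc = min(1.0, np.exp(min(log_r, 0.0)))
            acc_sum += acc
            n_prop += 1
            if self.rng.random() < acc:
                st.beta[g] = new_val
                self.eta, self.lse, self.cur_ll = eta_p, lse_p, ll_p
                self.accept_counts["beta2"][0] += 1
            self.accept_counts["beta2"][1] += 1
        if n_prop:
            self._adapt("beta2", acc_sum / n_prop)

    # -- pi ------------------------------------------------------------------
    def update_pi(self) -> None:
        st = self.state
        z = self.prior.z
        if z.shape[0] == 0:
            raise ValueError("cannot update pi with no genes")
        if self.cfg.variant == "modelII":
            self._update_pi_mh_model2()
            return
        if self.cfg.pi_update == "gibbs":
            prec = z.T @ z / st.sigma2 + np.eye(z.shape[1]) / st.vpi
            rhs = z.T @ (st.beta - st.b) / st.sigma2
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            noise = np.linalg.solve(chol.T, self.rng.standard_normal(z.shape[1]))
            st.pi = mean + noise
        else:
            s = self.scales["pi"]
            pi_p = st.pi + s * self.rng.standard_normal(z.shape[1])
            def logpost(pi):
                e = st.beta - st.b - z @ pi
                return (-0.5 * (e @ e) / st.sigma2
                        - 0.5 * (pi @ pi) / st.vpi)
            log_r = logpost(pi_p) - logpost(st.pi)
            acc = min(1.0, np.exp(min(log_r, 0.0)))
            if self.rng.random() < acc:
                st.pi = pi_p
                self.accept_counts["pi"][0] += 1
            self.accept_counts["pi"][1] += 1
            self._adapt("pi", acc)

    def _log_prior_beta_model2(self, pi, sigma2) -> float:
        from scipy.stats import norm
        st = self.state
        mu = self.prior.z @ pi
        sigma = np.sqrt(sigma2)
        zero = st.beta == 0
        lp = norm.logcdf(-mu[zero] / sigma).sum()
        lp += norm.logpdf(st.beta[~zero], mu[~zero], sigma).sum()
        return float(lp)

    def _update_pi_mh_model2(self) -> None:
        st = self.state
        s = self.scales["pi"]
        pi_p = st.pi + s * self.rng.standard_normal(st.pi.shape[0])
        log_r = (self._log_prior_beta_model2(pi_p, st.sigma2)
                 - 0.5 * (pi_p @ pi_p) / st.vpi
                 - self._log_prior_beta_model2(st.pi, st.sigma2)
                 + 0.5 * (st.pi @ st.pi) / st.vpi)
        acc = min(1.0, np.exp(min(log_r, 0.0)))
        if self.rng.random() < acc:
            st.pi = pi_p
            self.accept_counts["pi"][0] += 1
        self.accept_counts["pi"][1] += 1
        self._adapt("pi", acc)

    # -- variances ----------------------------------------------------------
    def update_variances(self) -> None:
        st = self.state
        h = self.prior.hyper
        n_g = self.n_genes
        if self.cfg.variant == "modelII":
            self._update_sigma2_mh_model2()
        else:
            e = st.beta - self.prior.z @ st.pi - st.b
            st.sigma2 = float(_draw_inv_gamma(
                self.rng, h.df_e + 0.5 * n_g, h.e + 0.5 * (e @ e)))
            q = np.linalg.solve(self.chol_a, st.b)
            st.tau2 = float(_draw_inv_gamma(
                self.rng, h.df_b + 0.5 * n_g, h.b + 0.5 * (q @ q)))
        st.vpi = float(_draw_inv_gamma(
            self.rng, 1.0 + 0.5 * st.pi.shape[0], h.p + 0.5 * (st.pi @ st.pi)))

    def _update_sigma2_mh_model2(self) -> None:
        from .prior_model import inv_gamma_logpdf
        st = self.state
        h = self.prior.hyper
        prop = st.sigma2 * np.exp(0.3 * self.rng.standard_normal())
        log_r = (self._log_prior_beta_model2(st.pi, prop)
                 + inv_gamma_logpdf(prop, h.df_e, h.e) + np.log(prop)
                 - self._log_prior_beta_model2(st.pi, st.sigma2)
                 - inv_gamma_logpdf(st.sigma2, h.df_e, h.e) - np.log(st.sigma2))
        if self.rng.random() < min(1.0, np.exp(min(log_r, 0.0))):
            st.sigma2 = float(prop)

    # -- alpha ----------------------------------------------------------------
    def update_alpha(self) -> None:
        st = self.state
        if self.X.shape[1] == 0:
            return
        s = self.scales["alpha"]
        if s == 0:
            warnings.warn("alpha proposal scale is 0; state unchanged",
                          stacklevel=2)
            return
        alpha_p = st.alpha + s * self.rng.standard_normal(self.X.shape[1])
        shift = self.X @ (alpha_p - st.alpha)
        eta_p = self.eta + shift
        ll_p, lse_p = self._ll_of_eta(eta_p)
        log_r = ll_p - self.cur_ll        # flat prior
        acc = min(1.0, np.exp(min(log_r, 0.0)))
        if self.rng.random() < acc:
            st.alpha = alpha_p
            self.base = self.base + shift
            self.eta, self.lse, self.cur_ll = eta_p, lse_p, ll_p
            self.accept_counts["alpha"][0] += 1
        self.accept_counts["alpha"][1] += 1
        self._adapt("alpha", acc)

    # -- adaptation ------------------------------------------------------------
    def _adapt(self, key: str, acc_prob: float) -> None:
        if not (self._adapting and self.cfg.adapt):
            return
        step = 1.0 / (1.0 + self._adapt_t) ** 0.6
        factor = np.exp(step * (acc_prob - self.cfg.target_accept))
        if key == "beta_b":
            sb, sbb = self.scales["beta_b"]
            self.scales["beta_b"] = (sb * factor, sbb * factor)
        else:
            self.scales[key] *= factor

    # -- driver ------------------------------------------------------------------
    def step(self) -> None:
        self.update_w()
        if self.cfg.variant == "modelII":
            self.update_beta_model2()
        else:
            self.update_beta_b()
        self.update_pi()
        self.update_variances()
        self.update_alpha()

    def run(self) -> ChainSamples:
        cfg = self.cfg
        n_scans = cfg.n_burnin + cfg.n_keep * cfg.thin
        keep_w = np.empty((cfg.n_keep, self.n_snps), dtype=np.int8)
        keep_beta = np.empty((cfg.n_keep, self.n_genes))
        keep_b = np.empty((cfg.n_keep, self.n_genes))
        keep_pi = np.empty((cfg.n_keep, self.state.pi.shape[0]))
        keep_alpha = np.empty((cfg.n_keep, self.state.alpha.shape[0]))
        keep_s2 = np.empty(cfg.n_keep)
        keep_t2 = np.empty(cfg.n_keep)
        t0 = time.perf_counter()
        kept = 0
        for t in range(n_scans):
            self._adapting = t < cfg.n_burnin
            self._adapt_t = t
            self.step()
            if t >= cfg.n_burnin and (t - cfg.n_burnin) % cfg.thin == 0:
                st = self.state
                keep_w[kept] = st.w
                keep_beta[kept] = st.beta
                keep_b[kept] = st.b
                keep_pi[kept] = st.pi
                keep_alpha[kept] = st.alpha
                keep_s2[kept] = st.sigma2
                keep_t2[kept] = st.tau2
                kept += 1
        elapsed = time.perf_counter() - t0
        rates = {k: (c[0] / c[1] if c[1] else float("nan"))
                 for k, c in self.accept_counts.items()}
        logger.info("MCMC: %d scans in %.1fs; acceptance %s",
                    n_scans, elapsed, rates)
        return ChainSamples(
            w=keep_w, beta=keep_beta, b=keep_b, pi=keep_pi, alpha=keep_alpha,
            sigma2=keep_s2, tau2=keep_t2,
            meta={"seed": cfg.seed, "n_burnin": cfg.n_burnin,
                  "n_keep": cfg.n_keep, "thin": cfg.thin,
                  "variant": cfg.variant, "elapsed_s": elapsed,
                  "acceptance": rates},
        )


def run_mcmc(data: StudyData, prior: PriorSpec, cfg: McmcConfig) -> ChainSamples:
    """Fit the model and return the retained post-burn-in scans."""
    return GibbsSampler(data, prior, cfg).run()


# ---------------------------------------------------------------------------
# functional wrappers: one-block updates on an explicit state (used in tests
# and for composing custom schedules)
# ---------------------------------------------------------------------------

def _one_shot(data, prior, cfg, state, rng, method: str) -> ModelState:
    sampler = GibbsSampler(data, prior, cfg or McmcConfig(), state=state, rng=rng)
    getattr(sampler, method)()
    return sampler.state


def update_W(state, data, rs, prior, rng, cfg=None) -> ModelState:
    """Redraw every SNP weight from its exact full conditional."""
    return _one_shot(data, prior, cfg, state, rng, "update_w")


def update_beta_b(state, data, rs, prior, cfg, rng) -> ModelState:
    return _one_shot(data, prior, cfg, state, rng, "update_beta_b")


def update_pi(state, prior, cfg, rng, data=None) -> ModelState:
    if data is None:
        raise ValueError("study data required (likelihood caches)")
    return _one_shot(data, prior, cfg, state, rng, "update_pi")


def update_variances(state, prior, rng, data=None, cfg=None) -> ModelState:
    if data is None:
        raise ValueError("study data required (likelihood caches)")
    return _one_shot(data, prior, cfg, state, rng, "update_variances")


def update_alpha(state, data, rs, cfg, rng, prior=None) -> ModelState:
    if prior is None:
        raise ValueError("prior required (sampler construction)")
    return _one_shot(data, prior, cfg, state, rng, "update_alpha")


def update_beta_modelII(state, data, rs, prior, cfg, rng) -> ModelState:
    if cfg is None or cfg.variant != "modelII":
        raise ValueError("update_beta_modelII requires cfg.variant='modelII'")
    return _one_shot(data, prior, cfg, state, rng, "update_beta_model2")
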