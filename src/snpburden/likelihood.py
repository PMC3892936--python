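"""Burden indices, linear predictors and the conditional logistic
log-likelihood over matched risk sets.

Each matched set contributes ``eta_case - log(sum_j exp(eta_j))`` where the
sum runs over the case and its matched controls; this conditions out any
per-set nuisance intercept, so only within-set contrasts of the linear
predictor matter.  The per-subject predictor is

    eta_i = X_i' alpha + sum_g coef_g * G(W_g, S_ig) + offset_i

with the gene burden index ``G(W_g, S_ig) = sum_s W_gs * S_igs`` and
``coef_g = exp(beta_g)`` under Model I (positivity avoids label switching
between (beta_g, W_g) and (beta_g, -W_g)) or ``coef_g = beta_g >= 0`` under
Model II.  All log-sum-exp reductions use pairwise ``logaddexp`` and are
numerically stable for arbitrary eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import ModelState, StudyData

__all__ = [
    "RiskSetIndex",
    "burden_index",
    "burden_matrix",
    "gene_coefficients",
    "linear_predictor",
    "cond_logistic_loglik",
    "loglik_delta_snp",
]


@dataclass
class RiskSetIndex:
    """Grouped view of matched sets.

    ``order`` lists subject indices grouped set-by-set, ``starts`` gives the
    offset of each set within ``order`` (suitable for ufunc.reduceat) and
    ``case_pos`` the position within ``order`` of each set's single case.
    """

    order: np.ndarray
    starts: np.ndarray
    case_pos: np.ndarray

    @classmethod
    def from_study(cls, data: StudyData) -> "RiskSetIndex":
        return cls.from_arrays(data.riskset, data.y)

    @classmethod
    def from_arrays(cls, riskset, y) -> "RiskSetIndex":
        riskset = np.asarray(riskset)
        y = np.asarray(y)
        order = np.argsort(riskset, kind="stable")
        sorted_rs = riskset[order]
        starts = np.flatnonzero(np.r_[True, sorted_rs[1:] != sorted_rs[:-1]])
        sizes = np.diff(np.r_[starts, len(order)])
        if (sizes < 2).any():
            raise ValueError("every risk set needs at least 2 members")
        case_mask = y[order] == 1
        counts = np.add.reduceat(case_mask.astype(int), starts)
        if (counts != 1).any():
            r = int(np.flatnonzero(counts != 1)[0])
            raise ValueError(f"risk set {sorted_rs[starts[r]]} has {counts[r]} cases")
        case_pos = np.flatnonzero(case_mask)
        return cls(order=order, starts=starts, case_pos=case_pos)

    @property
    def n_sets(self) -> int:
        return len(self.starts)


def burden_index(w_g, s_ig) -> float:
    """Signed burden index sum_s W_gs * S_igs for one subject and one gene."""
    w_g = np.asarray(w_g)
    s_ig = np.asarray(s_ig)
    if w_g.shape != s_ig.shape:
        raise ValueError("weight and genotype vectors differ in length")
    return float(w_g @ s_ig)


def burden_matrix(w, genotypes, snp_gene, n_genes: int | None = None) -> np.ndarray:
    """(N_I, N_G) matrix of per-gene burden indices for all subjects."""
    w = np.asarray(w, dtype=float)
    snp_gene = np.asarray(snp_gene)
    if n_genes is None:
        n_genes = int(snp_gene.max()) + 1
    out = np.zeros((genotypes.shape[0], n_genes))
    ws = genotypes * w[None, :]
    np.add.at(out.T, snp_gene, ws.T)
    return out


def gene_coefficients(state: ModelState, variant: str = "modelI") -> np.ndarray:
    """Multiplier of the burden index per gene: exp(beta) (Model I) or beta
    itself, constrained nonnegative (Model II)."""
    if variant == "modelI":
        return np.exp(state.beta)
    if variant == "modelII":
        if (state.beta < 0).any():
            raise ValueError("Model II requires beta >= 0")
        return state.beta.astype(float)
    raise ValueError(f"unknown variant {variant!r}")


def linear_predictor(state: ModelState, data: StudyData,
                     variant: str = "modelI") -> np.ndarray:
    """Per-subject linear predictor eta_i."""
    coef = gene_coefficients(state, variant)
    g_mat = burden_matrix(state.w, data.genotypes, data.snp_gene, data.n_genes)
    eta = data.offset + g_mat @ coef
    if data.x.shape[1]:
        eta = eta + data.x @ state.alpha
    return eta


def cond_logistic_loglik(eta: np.ndarray, rs: RiskSetIndex) -> float:
    """Conditional logistic log-likelihood sum_r [eta_case - logsumexp_set]."""
    es = np.asarray(eta, dtype=float)[rs.order]
    lse = np.logaddexp.reduceat(es, rs.starts)
    return float(es[rs.case_pos].sum() - lse.sum())


def loglik_delta_snp(state: ModelState, data: StudyData, rs: RiskSetIndex,
                     gene: int, snp: int, new_weight: int,
                     variant: str = "modelI",
                     eta: np.ndarray | None = None) -> float:
    """Exact change in the conditional log-likelihood from setting
    ``W[snp] = new_weight`` with all other parameters held fixed.

    Only risk sets containing a carrier of the SNP contribute, so the update
    touches O(carrier sets) subjects rather than the whole study.  ``eta``
    may supply the current linear predictor to avoid recomputation.
    """
    if new_weight not in (-1, 0, 1):
        raise ValueError("new_weight must be -1, 0 or +1")
    if data.snp_gene[snp] != gene:
        raise ValueError(f"SNP {snp} does not belong to gene {gene}")
    old = int(state.w[snp])
    if new_weight == old:
        return 0.0
    if eta is None:
        eta = linear_predictor(state, data, variant)
    coef = gene_coefficients(state, variant)[gene]
    delta = coef * (new_weight - old)
    s_col = data.genotypes[:, snp].astype(float)
    es = eta[rs.order]
    ds = delta * s_col[rs.order]
    carrier_sets = np.unique(
        np.searchsorted(rs.starts, np.flatnonzero(ds != 0.0), side="right") - 1)
    if carrier_sets.size == 0:
        return 0.0
    total = 0.0
    bounds = np.r_[rs.starts, len(rs.order)]
    for r in carrier_sets:
        lo, hi = bounds[r], bounds[r + 1]
        old_lse = np.logaddexp.reduce(es[lo:hi])
        new_lse = np.logaddexp.reduce(es[lo:hi] + ds[lo:hi])
        total += ds[rs.case_pos[r]] - (new_lse - old_lse)  # one case per set
    return float(total)
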