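"""Prior construction: per-SNP weight probabilities, the gene-level design
matrix Z and similarity matrix A, and inverse-gamma hyperprior densities.

The per-SNP weight prior places probability ``phi_d * (Nbar + c)/(N_S_g + c)``
on each signed weight ``d in {-1, +1}`` and the remainder on exclusion
(``W = 0``).  Scaling by gene size keeps the expected number of SNPs entering
the model roughly constant across genes, so a 51-SNP gene is not favored over
a 1-SNP gene merely by offering more candidates.  An alternative literal
convention dividing ``phi_d`` by ``N_S_g + c`` without the ``Nbar + c``
numerator is available as ``scaling="eq7_literal"``; whichever convention is
configured is used consistently for both sampling and Bayes-factor prior
odds.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .core_types import AnnotationMatrix, PriorSpec, HyperParams, StudyData

__all__ = [
    "snp_prior_probs",
    "snp_prior_odds",
    "gene_prior_inclusion",
    "build_A",
    "build_Z",
    "inv_gamma_logpdf",
    "make_prior",
]

logger = logging.getLogger(__name__)


def snp_prior_probs(n_snps_g: int, nbar: float, c: float,
                    phi_minus: float, phi_plus: float,
                    scaling: str = "eq5", cap: float | None = 0.5):
    """Prior probabilities (p_minus, p_zero, p_plus) for one SNP's weight.

    Parameters
    ----------
    n_snps_g : number of SNPs in the gene (N_S_g >= 1).
    nbar : average number of SNPs per gene across the study.
    c : small-count stabilizer (conventionally the minimum SNPs per gene).
    phi_minus, phi_plus : base prior probabilities of protective (-1) and
        deleterious (+1) assignment, phi_minus + phi_plus < 1.
    scaling : "eq5" multiplies phi by (nbar + c)/(n_snps_g + c);
        "eq7_literal" uses phi/(n_snps_g + c).
    cap : if the scaled inclusion mass p_minus + p_plus would exceed this
        value the two are shrunk proportionally (with a warning); pass None
        to disable capping, in which case a negative p_zero is an error.
    """
    if n_snps_g < 1:
        raise ValueError("n_snps_g must be >= 1")
    if phi_minus < 0 or phi_plus < 0 or phi_minus + phi_plus >= 1:
        raise ValueError("need phi_minus, phi_plus >= 0 and phi_minus + phi_plus < 1")
    if c <= 0:
        raise ValueError("c must be > 0")
    if scaling == "eq5":
        factor = (nbar + c) / (n_snps_g + c)
    elif scaling == "eq7_literal":
        factor = 1.0 / (n_snps_g + c)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    p_minus = phi_minus * factor
    p_plus = phi_plus * factor
    total = p_minus + p_plus
    if cap is not None and total > cap:
        warnings.warn(
            f"per-SNP prior inclusion mass {total:.3f} exceeds cap {cap}; "
            "shrinking proportionally", stacklevel=2)
        shrink = cap / total
        p_minus *= shrink
        p_plus *= shrink
        total = cap
    p_zero = 1.0 - total
    if p_zero < 0:
        raise ValueError(
            f"prior exclusion probability negative ({p_zero:.3f}); "
            "enable capping or reduce phi")
    return p_minus, p_zero, p_plus


def snp_prior_odds(n_snps_g: int, nbar: float, c: float,
                   phi_minus: float, phi_plus: float,
                   scaling: str = "eq5", cap: float | None = 0.5) -> float:
    """Prior odds Pr(W != 0)/Pr(W = 0) under the configured convention.

    This is the denominator of the SNP Bayes factor; using the same
    convention as :func:`snp_prior_probs` guarantees BF = 1 when the
    posterior reproduces the prior.
    """
    p_minus, p_zero, p_plus = snp_prior_probs(
        n_snps_g, nbar, c, phi_minus, phi_plus, scaling=scaling, cap=cap)
    return (p_minus + p_plus) / p_zero


def gene_prior_inclusion(n_snps_g: int, nbar: float, c: float,
                         phi_minus: float, phi_plus: float,
                         scaling: str = "eq5", cap: float | None = 0.5) -> float:
    """Prior probability that at least one of the gene's SNPs is included,
    1 - (1 - p_incl)^N_S_g with per-SNP independence."""
    p_minus, _, p_plus = snp_prior_probs(
        n_snps_g, nbar, c, phi_minus, phi_plus, scaling=scaling, cap=cap)
    return 1.0 - (1.0 - (p_minus + p_plus)) ** n_snps_g


def prior_prob_table(prior: PriorSpec, snps_per_gene: np.ndarray) -> np.ndarray:
    """(n_genes, 3) array of (p_minus, p_zero, p_plus) rows, one per gene."""
    out = np.empty((len(snps_per_gene), 3))
    for g, n in enumerate(snps_per_gene):
        out[g] = snp_prior_probs(int(n), prior.nbar, prior.c,
                                 prior.phi_minus, prior.phi_plus,
                                 scaling=prior.scaling)
    return out


def build_A(ann: AnnotationMatrix, method: str = "correlation",
            jitter_start: float = 1e-8) -> np.ndarray:
    """Gene-gene similarity matrix from binary annotation rows.

    method="correlation" (default) takes the Pearson correlation between
    annotation rows; negative correlations are retained.  method="jaccard"
    uses 1 - Jaccard distance, always nonnegative.  The result is symmetrized
    and, if not positive-definite, repaired by adding the smallest diagonal
    jitter (doubling from ``jitter_start``) that lifts the minimum eigenvalue
    above 1e-10, then rescaled to unit diagonal.
    """
    m = ann.m.astype(float)
    n_g = m.shape[0]
    if n_g < 2:
        raise ValueError("need at least 2 genes")
    if method == "correlation":
        sd = m.std(axis=1)
        if (sd == 0).any():
            g = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"gene {ann.genes[g]} has a constant annotation row; "
                "correlation undefined")
        a = np.corrcoef(m)
    elif method == "jaccard":
        inter = m @ m.T
        sizes = m.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        np.fill_diagonal(a, 1.0)
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    # PD repair by minimal diagonal inflation
    delta = jitter_start
    eigmin = np.linalg.eigvalsh(a).min()
    applied = 0.0
    while eigmin <= 1e-10:
        a = a + delta * np.eye(n_g)
        applied += delta
        delta *= 2
        eigmin = np.linalg.eigvalsh(a).min()
    if applied > 0:
        logger.info("similarity matrix repaired with diagonal jitter %.3g", applied)
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        np.fill_diagonal(a, 1.0)
    return a


def build_Z(ann: AnnotationMatrix, selected_terms) -> np.ndarray:
    """Gene-level prior design matrix: an intercept column of ones followed by
    the binary memberships of the selected annotation terms."""
    selected_terms = list(selected_terms)
    index = {t: j for j, t in enumerate(ann.terms)}
    missing = [t for t in selected_terms if t not in index]
    if missing:
        avail = ", ".join(ann.terms[:10])
        raise KeyError(
            f"term(s) {missing} not in annotation (available: {avail}"
            + (", ..." if ann.n_terms > 10 else "") + ")")
    cols = [np.ones(ann.n_genes)]
    cols += [ann.m[:, index[t]].astype(float) for t in selected_terms]
    return np.column_stack(cols)


def inv_gamma_logpdf(x: float, df: float, scale: float) -> float:
    """Log density of the inverse gamma in shape (``df``)/scale form:
    p(x) = scale^df / Gamma(df) * x^(-df-1) * exp(-scale/x), x > 0.

    Returns -inf for x <= 0 rather than raising.
    """
    if df <= 0 or scale <= 0:
        raise ValueError("df and scale must be > 0")
    x = np.asarray(x, dtype=float)
    from scipy.special import gammaln
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            x > 0,
            df * np.log(scale) - gammaln(df) - (df + 1) * np.log(np.where(x > 0, x, 1.0))
            - scale / np.where(x > 0, x, 1.0),
            -np.inf,
        )
    return float(out) if out.ndim == 0 else out


def make_prior(data: StudyData, ann: AnnotationMatrix, z_terms,
               phi_plus: float = 0.05, phi_minus: float = 0.05,
               c="auto", scaling: str = "eq5",
               similarity_method: str = "correlation",
               hyper: HyperParams | None = None,
               jitter_start: float = 1e-8) -> PriorSpec:
    """Assemble a PriorSpec from study data and annotations.

    ``c="auto"`` uses the minimum SNP count over genes; ``nbar`` is always the
    study average SNPs per gene.
    """
    nsg = data.snps_per_gene
    c_val = float(nsg.min()) if c == "auto" else float(c)
    return PriorSpec(
        phi_plus=phi_plus, phi_minus=phi_minus, c=c_val,
        nbar=float(nsg.mean()),
        z=build_Z(ann, z_terms),
        a=build_A(ann, method=similarity_method, jitter_start=jitter_start),
        hyper=hyper or HyperParams(), scaling=scaling,
    )
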