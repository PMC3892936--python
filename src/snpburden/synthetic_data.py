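"""Synthetic matched case-control study generator.

Emulates the structure of a candidate-gene study of second primary breast
cancer: 38 genes carrying 504 tag SNPs (1 to 51 per gene), ~700 matched risk
sets of 2-3 subjects, binary ontology-style annotations over 860 terms, and
a generative model in which gene log-relative-risk coefficients are drawn
around an ontology-informed mean Z'pi with correlated (tau, similarity A)
and independent (sigma) components, SNP weights are drawn from the size-
balanced -1/0/+1 prior, and within each risk set one member is designated
the case with probability proportional to its relative risk.

Genotypes are independent Hardy-Weinberg draws at minor-allele frequencies
uniform on a configurable range; real linkage disequilibrium, real covariate
distributions and counter-matching offsets are deliberately not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_types import AnnotationMatrix, ChainSamples, PriorSpec, StudyData
from .likelihood import RiskSetIndex, burden_matrix
from .prior_model import make_prior, prior_prob_table

__all__ = [
    "SimConfig",
    "TruthRecord",
    "DEFAULT_SNPS_PER_GENE",
    "simulate_annotations",
    "simulate_genotypes",
    "simulate_truth",
    "assign_cases",
    "simulate_study",
    "write_study",
    "run_simulation_study",
]

logger = logging.getLogger(__name__)

# Fixed per-gene SNP counts: 38 genes, 504 SNPs, min 1, max 51, mean ~13.3,
# exercising both the c = min(N_S_g) rule and the gene-size prior scaling.
DEFAULT_SNPS_PER_GENE = (
    1, 1, 2, 3, 3, 4, 5, 5, 6, 7, 7, 8, 8, 9, 9, 10, 10, 11, 11, 12, 12, 13,
    13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 23, 24, 25, 26, 51,
)

# Names for the four reserved prior-covariate terms (ontology-like labels).
Z_TERM_NAMES = ("term_dna_damage_checkpoint", "term_mre11_complex",
                "term_nhej_repair", "term_neg_reg_cell_cycle")


@dataclass
class SimConfig:
    """Generative settings.

    Defaults follow the reference simulation design: per-term second-level
    effects (0.25, 0.5, 0.75, 1) with intercept -2, sigma = tau = 0.5,
    phi_- = phi_+ = 0.05, c = 1, 700 risk sets (70% of size 2, 30% of
    size 3), Hardy-Weinberg genotypes at MAF uniform on (0.05, 0.5).
    """

    n_genes: int = 38
    snps_per_gene: tuple = DEFAULT_SNPS_PER_GENE
    n_terms: int = 860
    n_risksets: int = 700
    riskset_size_probs: tuple = ((2, 0.7), (3, 0.3))
    maf_range: tuple = (0.05, 0.5)
    pi_true: tuple = (-2.0, 0.25, 0.5, 0.75, 1.0)
    sigma_true: float = 0.5
    tau_true: float = 0.5
    phi_plus: float = 0.05
    phi_minus: float = 0.05
    c: float = 1.0
    prior_scaling: str = "eq5"
    n_covariates: int = 1
    alpha_true: tuple = (0.5,)
    offset_sd: float = 0.0
    ld_copy: float = 0.0
    n_blocks: int = 8
    seed: int = 0

    def __post_init__(self):
        if len(self.snps_per_gene) != self.n_genes:
            raise ValueError("snps_per_gene length must equal n_genes")
        if min(self.snps_per_gene) < 1:
            raise ValueError("every gene needs at least one SNP")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.ld_copy < 1:
            raise ValueError("ld_copy must lie in [0, 1)")
        if self.n_terms < len(Z_TERM_NAMES):
            raise ValueError("n_terms must cover the reserved prior-covariate terms")
        if len(self.alpha_true) != self.n_covariates:
            raise ValueError("alpha_true length must equal n_covariates")

    @property
    def n_snps(self) -> int:
        return int(sum(self.snps_per_gene))


@dataclass
class TruthRecord:
    """Ground truth for one simulated dataset."""

    w_true: np.ndarray
    beta_true: np.ndarray
    b_true: np.ndarray
    pi_true: np.ndarray
    alpha_true: np.ndarray

    @property
    def causal_snps(self) -> np.ndarray:
        return np.flatnonzero(self.w_true != 0)

    def causal_genes(self, snp_gene, n_genes: int) -> np.ndarray:
        mask = np.zeros(n_genes, dtype=bool)
        mask[np.asarray(snp_gene)[self.w_true != 0]] = True
        return np.flatnonzero(mask)


def simulate_annotations(cfg: SimConfig, rng: np.random.Generator
                         ) -> AnnotationMatrix:
    """Block-structured binary gene-by-term matrix.

    Genes are grouped into ``n_blocks`` simulated pathways; terms are mostly
    block-specific, so genes sharing a block share memberships and derive a
    high similarity, while cross-block pairs are near-uncorrelated.  The
    first four terms are the reserved prior covariates, each annotated to a
    random subset of genes.
    """
    n_g, n_t = cfg.n_genes, cfg.n_terms
    block = rng.integers(0, cfg.n_blocks, size=n_g)
    m = np.zeros((n_g, n_t), dtype=np.int8)
    # reserved prior-covariate terms: each tags ~1/4 of the genes
    for j in range(len(Z_TERM_NAMES)):
        members = rng.random(n_g) < 0.25
        if not members.any():
            members[rng.integers(n_g)] = True
        m[members, j] = 1
    # remaining terms: block-specific with high within-block inclusion plus
    # background noise, producing similarities spanning roughly [0, 0.8]
    for j in range(len(Z_TERM_NAMES), n_t):
        bj = rng.integers(0, cfg.n_blocks)
        in_block = block == bj
        prob = np.where(in_block, 0.75, 0.02)
        m[:, j] = rng.random(n_g) < prob
    # no gene may end up unannotated
    empty = m.sum(axis=1) == 0
    if empty.any():
        m[empty, rng.integers(len(Z_TERM_NAMES), n_t)] = 1
    genes = [f"gene{i+1}" for i in range(n_g)]
    terms = list(Z_TERM_NAMES) + [f"term{j+1}" for j in range(n_t - len(Z_TERM_NAMES))]
    return AnnotationMatrix(genes=genes, terms=terms, m=m)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator,
                       n_subjects: int) -> np.ndarray:
    """Hardy-Weinberg genotypes at per-SNP MAFs uniform on ``maf_range``.

    SNPs are independent by default.  With ``ld_copy > 0`` a one-parameter
    haplotype-copying scheme induces within-gene linkage disequilibrium:
    each of a subject's two haplotypes carries, at every SNP after the
    gene's first, the same allele as at the previous SNP with probability
    ``ld_copy`` (a fresh allele-frequency draw otherwise).
    """
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_snps)
    if cfg.ld_copy == 0.0:
        return rng.binomial(2, maf, size=(n_subjects, cfg.n_snps)).astype(np.int8)
    snp_gene = np.repeat(np.arange(cfg.n_genes), np.asarray(cfg.snps_per_gene))
    hap = np.empty((2, n_subjects, cfg.n_snps), dtype=np.int8)
    for j in range(cfg.n_snps):
        fresh = rng.random((2, n_subjects)) < maf[j]
        if j > 0 and snp_gene[j] == snp_gene[j - 1]:
            copy = rng.random((2, n_subjects)) < cfg.ld_copy
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
        else:
            hap[:, :, j] = fresh
    return hap.sum(axis=0).astype(np.int8)


def simulate_truth(cfg: SimConfig, z: np.ndarray, a: np.ndarray,
                   rng: np.random.Generator) -> TruthRecord:
    """Draw gene coefficients beta = Z pi + b + e (b ~ MVN(0, tau^2 A),
    e ~ N(0, sigma^2)) and SNP weights from the size-balanced prior."""
    n_g = cfg.n_genes
    pi = np.asarray(cfg.pi_true, dtype=float)
    if z.shape[1] != pi.shape[0]:
        raise ValueError("pi_true length must match Z columns (incl. intercept)")
    chol = np.linalg.cholesky(a)
    b = cfg.tau_true * (chol @ rng.standard_normal(n_g))
    e = cfg.sigma_true * rng.standard_normal(n_g)
    beta = z @ pi + b + e
    nsg = np.asarray(cfg.snps_per_gene)
    prior = PriorSpec(phi_plus=cfg.phi_plus, phi_minus=cfg.phi_minus,
                      c=cfg.c, nbar=float(nsg.mean()), z=z, a=a,
                      scaling=cfg.prior_scaling)
    probs = prior_prob_table(prior, nsg)
    snp_gene = np.repeat(np.arange(n_g), nsg)
    u = rng.random(cfg.n_snps)
    p = probs[snp_gene]
    w = np.where(u < p[:, 0], -1, np.where(u < p[:, 0] + p[:, 1], 0, 1))
    return TruthRecord(w_true=w.astype(np.int8), beta_true=beta, b_true=b,
                       pi_true=pi,
                       alpha_true=np.asarray(cfg.alpha_true, dtype=float))


def assign_cases(eta: np.ndarray, rs: RiskSetIndex,
                 rng: np.random.Generator) -> np.ndarray:
    """Label exactly one member of each risk set as the case, drawn with
    probability exp(eta_j) / sum_k exp(eta_k) within the set."""
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("eta must be finite")
    y = np.zeros(eta.shape[0], dtype=np.int8)
    es = eta[rs.order]
    bounds = np.r_[rs.starts, len(rs.order)]
    for r in range(rs.n_sets):
        lo, hi = bounds[r], bounds[r + 1]
        p = np.exp(es[lo:hi] - es[lo:hi].max())
        p /= p.sum()
        pick = rng.choice(hi - lo, p=p)
        y[rs.order[lo + pick]] = 1
    return y


def simulate_study(cfg: SimConfig, rng: np.random.Generator | None = None,
                   ann: AnnotationMatrix | None = None,
                   truth: TruthRecord | None = None
                   ) -> tuple[StudyData, TruthRecord, AnnotationMatrix]:
    """Generate one complete dataset.

    ``ann`` and ``truth`` may be supplied to reuse a truth realization across
    replicate datasets (new genotypes and case assignments each call).
    """
    from .prior_model import build_A, build_Z
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if ann is None:
        ann = simulate_annotations(cfg, rng)
    z = build_Z(ann, Z_TERM_NAMES)
    a = build_A(ann)
    if truth is None:
        truth = simulate_truth(cfg, z, a, rng)

    sizes = np.array([s for s, _ in cfg.riskset_size_probs])
    probs = np.array([p for _, p in cfg.riskset_size_probs], dtype=float)
    probs /= probs.sum()
    set_sizes = rng.choice(sizes, size=cfg.n_risksets, p=probs)
    n_subj = int(set_sizes.sum())
    riskset = np.repeat(np.arange(cfg.n_risksets), set_sizes)

    geno = simulate_genotypes(cfg, rng, n_subj)
    x = rng.standard_normal((n_subj, cfg.n_covariates)) \
        if cfg.n_covariates else np.zeros((n_subj, 0))
    offset = (cfg.offset_sd * rng.standard_normal(n_subj)
              if cfg.offset_sd > 0 else np.zeros(n_subj))

    snp_gene = np.repeat(np.arange(cfg.n_genes), np.asarray(cfg.snps_per_gene))
    g_mat = burden_matrix(truth.w_true, geno, snp_gene, cfg.n_genes)
    eta = offset + g_mat @ np.exp(truth.beta_true)
    if cfg.n_covariates:
        eta = eta + x @ truth.alpha_true

    y0 = np.zeros(n_subj, dtype=np.int8)
    y0[np.r_[0, np.cumsum(set_sizes)[:-1]]] = 1   # placeholder for indexing
    rs = RiskSetIndex.from_arrays(riskset, y0)
    y = assign_cases(eta, rs, rng)

    snp_labels = [f"snp{j+1}" for j in range(cfg.n_snps)]
    data = StudyData(y=y, x=x, genotypes=geno, snp_gene=snp_gene,
                     riskset=riskset, offset=offset,
                     snp_labels=snp_labels, gene_labels=list(ann.genes))
    return data, truth, ann


def write_study(data: StudyData, ann: AnnotationMatrix, out_dir) -> dict:
    """Write genotype/subject/map/annotation TSVs consumable by the fitter.
    Returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.tsv"
             for k in ("genotypes", "subjects", "snp_map", "annotations")}
    geno = pd.DataFrame(data.genotypes, columns=data.snp_labels)
    geno.insert(0, "subject_id", data.subject_ids)
    geno.to_csv(paths["genotypes"], sep="\t", index=False)
    subj = pd.DataFrame({
        "subject_id": data.subject_ids,
        "riskset_id": [f"rs{r}" for r in data.riskset],
        "case": data.y, "offset": data.offset,
    })
    for k, name in enumerate(data.covariate_names):
        subj[name] = data.x[:, k]
    subj.to_csv(paths["subjects"], sep="\t", index=False)
    pd.DataFrame({
        "snp_id": data.snp_labels,
        "gene_id": [data.gene_labels[g] for g in data.snp_gene],
    }).to_csv(paths["snp_map"], sep="\t", index=False)
    annot = pd.DataFrame(ann.m, columns=ann.terms)
    annot.insert(0, "gene_id", ann.genes)
    annot.to_csv(paths["annotations"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# replicated simulation study
# ---------------------------------------------------------------------------

def run_simulation_study(cfg: SimConfig, n_truths: int, n_reps: int,
                         mcmc_cfg=None, seed: int | None = None,
                         progress: bool = False) -> dict:
    """Generate ``n_truths`` truth realizations x ``n_reps`` replicate
    datasets each, fit the model to every dataset and aggregate operating
    characteristics by true-weight class.

    Returns a dict with DataFrames ``snp_summary`` (rows: true W = -1/0/+1;
    columns: average count, average posterior Pr(W = -1/0/+1) as row
    percentages, and percentages of SNPs with BF > 3/20/150) and
    ``gene_summary`` (rows: truly included / not included genes; columns:
    average count, posterior inclusion percentages and gene-BF percentages),
    mirroring the standard operating-characteristics layout, plus the raw
    per-replicate records.
    """
    from .posterior_summary import gene_bf, snp_bf
    from .sampler import McmcConfig, run_mcmc

    if mcmc_cfg is None:
        mcmc_cfg = McmcConfig()
    if seed is None:
        seed = cfg.seed
    master = np.random.default_rng(seed)

    snp_rows, gene_rows = [], []
    for it in range(n_truths):
        truth_rng = np.random.default_rng(master.integers(2**31 - 1))
        ann = simulate_annotations(cfg, truth_rng)
        from .prior_model import build_A, build_Z
        z = build_Z(ann, Z_TERM_NAMES)
        a = build_A(ann)
        truth = simulate_truth(cfg, z, a, truth_rng)
        for rep in range(n_reps):
            rep_rng = np.random.default_rng(master.integers(2**31 - 1))
            data, _, _ = simulate_study(cfg, rng=rep_rng, ann=ann, truth=truth)
            prior = make_prior(data, ann, Z_TERM_NAMES,
                               phi_plus=cfg.phi_plus, phi_minus=cfg.phi_minus,
                               c=cfg.c, scaling=cfg.prior_scaling)
            fit_cfg = McmcConfig(**{**mcmc_cfg.__dict__,
                                    "seed": int(master.integers(2**31 - 1))})
            chain = run_mcmc(data, prior, fit_cfg)
            if progress:
                logger.info("truth %d rep %d done", it + 1, rep + 1)
            nsg = data.snps_per_gene
            p_m = (chain.w == -1).mean(axis=0)
            p_p = (chain.w == 1).mean(axis=0)
            bfs = np.array([snp_bf(chain, prior, nsg, int(data.snp_gene[j]), j)
                            for j in range(data.n_snps)])
            for j in range(data.n_snps):
                snp_rows.append({
                    "truth": it, "rep": rep, "snp": j,
                    "w_true": int(truth.w_true[j]),
                    "p_minus": p_m[j], "p_zero": 1 - p_m[j] - p_p[j],
                    "p_plus": p_p[j], "bf": bfs[j],
                })
            included = chain.w != 0
            gene_in = np.zeros((chain.n_scans, data.n_genes), dtype=bool)
            np.logical_or.at(gene_in.T, data.snp_gene, included.T)
            p_gene = gene_in.mean(axis=0)
            gbfs = np.array([gene_bf(chain, prior, nsg, data.snp_gene, g)
                             for g in range(data.n_genes)])
            causal_genes = set(truth.causal_genes(data.snp_gene, data.n_genes))
            for g in range(data.n_genes):
                gene_rows.append({
                    "truth": it, "rep": rep, "gene": g,
                    "included_true": g in causal_genes,
                    "p_included": p_gene[g], "bf": gbfs[g],
                })

    snp_df = pd.DataFrame(snp_rows)
    gene_df = pd.DataFrame(gene_rows)
    n_fits = n_truths * n_reps

    def pct(x):
        return 100.0 * np.mean(x)

    srows = []
    for w_true in (-1, 0, 1):
        sub = snp_df[snp_df["w_true"] == w_true]
        if sub.empty:
            continue
        srows.append({
            "w_true": w_true,
            "avg_count": len(sub) / n_fits,
            "post_minus_pct": pct(sub["p_minus"]),
            "post_zero_pct": pct(sub["p_zero"]),
            "post_plus_pct": pct(sub["p_plus"]),
            "bf_gt3_pct": pct(sub["bf"] > 3),
            "bf_gt20_pct": pct(sub["bf"] > 20),
            "bf_gt150_pct": pct(sub["bf"] > 150),
        })
    grows = []
    for inc in (False, True):
        sub = gene_df[gene_df["included_true"] == inc]
        if sub.empty:
            continue
        grows.append({
            "included_true": inc,
            "avg_count": len(sub) / n_fits,
            "post_not_included_pct": pct(1 - sub["p_included"]),
            "post_included_pct": pct(sub["p_included"]),
            "bf_gt3_pct": pct(sub["bf"] > 3),
            "bf_gt20_pct": pct(sub["bf"] > 20),
            "bf_gt150_pct": pct(sub["bf"] > 150),
        })
    return {
        "snp_summary": pd.DataFrame(srows),
        "gene_summary": pd.DataFrame(grows),
        "snp_records": snp_df,
        "gene_records": gene_df,
    }
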