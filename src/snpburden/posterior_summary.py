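"""Bayes factors, posterior inclusion tabulations and the variance-partition
("spatiality") summary.

The SNP Bayes factor divides the posterior odds of inclusion (the scan
frequency of W_gs != 0, with a 0.5 pseudo-count on both inclusion and
exclusion counts so chains that never/always include a SNP still yield a
finite BF) by the prior odds under the configured scaling convention.  The
gene Bayes factor does the same for the event "at least one SNP of the gene
is included", whose prior probability is 1 - (1 - p_incl)^N_S_g.  Evidence
grades follow the conventional thresholds: BF > 3 positive, > 20 strong,
> 150 very strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_types import ChainSamples, PriorSpec, StudyData
from .prior_model import (gene_prior_inclusion, prior_prob_table,
                          snp_prior_odds)

__all__ = [
    "SummaryTables",
    "snp_bf",
    "gene_bf",
    "evidence_grade",
    "spatiality",
    "tabulate",
]

_PSEUDO = 0.5


@dataclass
class SummaryTables:
    """Tabulated posterior quantities.

    ``snp_table``: per SNP, posterior Pr(W = -1/0/+1) and BF.
    ``gene_table``: per gene, posterior inclusion probability, BF, posterior
    mean/SD of beta and mean number of included SNPs.
    ``params``: posterior mean/SD of alpha, pi, sigma2, tau2.
    ``snp_count_dist`` / ``gene_count_dist``: posterior distributions of the
    number of SNPs / genes included per scan.
    """

    snp_table: pd.DataFrame
    gene_table: pd.DataFrame
    params: pd.DataFrame
    snp_count_dist: pd.DataFrame
    gene_count_dist: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.snp_table.to_csv(out / "snp_table.tsv", sep="\t", index=False)
        self.gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
        self.params.to_csv(out / "params.tsv", sep="\t", index=False)
        pd.concat(
            [self.snp_count_dist.assign(unit="snp"),
             self.gene_count_dist.assign(unit="gene")]
        ).to_csv(out / "counts_hist.tsv", sep="\t", index=False)

    def plot(self, out_dir) -> None:
        """Bar plots of the posterior count distributions and per-unit BFs."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, dist, label in zip(
                axes, (self.gene_count_dist, self.snp_count_dist),
                ("genes included", "SNPs included")):
            ax.bar(dist["count"], dist["probability"], color="steelblue")
            ax.set_xlabel(label)
            ax.set_ylabel("posterior probability")
        fig.tight_layout()
        fig.savefig(out / "counts_hist.png", dpi=120)
        plt.close(fig)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].bar(range(len(self.gene_table)), self.gene_table["bf"],
                    color="darkorange")
        axes[0].axhline(3, ls="--", c="gray")
        axes[0].set_xlabel("gene")
        axes[0].set_ylabel("Bayes factor")
        axes[1].bar(range(len(self.snp_table)), self.snp_table["bf"],
                    color="seagreen")
        axes[1].axhline(3, ls="--", c="gray")
        axes[1].set_xlabel("SNP")
        fig.tight_layout()
        fig.savefig(out / "bayes_factors.png", dpi=120)
        plt.close(fig)


def _posterior_odds(n_in: float, n_total: int) -> float:
    return (n_in + _PSEUDO) / (n_total - n_in + _PSEUDO)


def snp_bf(chain: ChainSamples, prior: PriorSpec, snps_per_gene, gene: int,
           snp: int) -> float:
    """Bayes factor for inclusion of one SNP (posterior odds of W != 0 over
    prior odds)."""
    if chain.n_scans == 0:
        raise ValueError("empty chain")
    n_in = int((chain.w[:, snp] != 0).sum())
    post = _posterior_odds(n_in, chain.n_scans)
    pri = snp_prior_odds(int(snps_per_gene[gene]), prior.nbar, prior.c,
                         prior.phi_minus, prior.phi_plus, scaling=prior.scaling)
    if pri == 0.0:      # zero prior inclusion mass: BF undefined
        return float("nan")
    return post / pri


def gene_bf(chain: ChainSamples, prior: PriorSpec, snps_per_gene, snp_gene,
            gene: int) -> float:
    """Bayes factor for the event that at least one SNP of the gene is
    included."""
    if chain.n_scans == 0:
        raise ValueError("empty chain")
    cols = np.flatnonzero(np.asarray(snp_gene) == gene)
    n_in = int((chain.w[:, cols] != 0).any(axis=1).sum())
    post = _posterior_odds(n_in, chain.n_scans)
    p_any = gene_prior_inclusion(int(snps_per_gene[gene]), prior.nbar, prior.c,
                                 prior.phi_minus, prior.phi_plus,
                                 scaling=prior.scaling)
    if p_any == 0.0:    # zero prior inclusion mass: BF undefined
        return float("nan")
    return post / (p_any / (1.0 - p_any))


def evidence_grade(bf: float) -> str:
    """Qualitative grade: >3 positive, >20 strong, >150 very strong."""
    if bf < 0:
        raise ValueError("Bayes factor must be nonnegative")
    if bf > 150:
        return "very strong"
    if bf > 20:
        return "strong"
    if bf > 3:
        return "positive"
    return "none"


def spatiality(sigma2: float, tau2: float) -> float:
    """Fraction tau2/(sigma2 + tau2) of residual gene-level variance carried
    by the ontology-derived correlation structure."""
    if sigma2 <= 0 or tau2 <= 0:
        raise ValueError("variance components must be > 0")
    return tau2 / (sigma2 + tau2)


def tabulate(chain: ChainSamples, prior: PriorSpec,
             data: StudyData) -> SummaryTables:
    """Compute all posterior summaries from a chain."""
    if chain.n_scans == 0:
        raise ValueError("empty chain")
    snp_gene = np.asarray(data.snp_gene)
    nsg = data.snps_per_gene
    n_scans = chain.n_scans

    p_minus = (chain.w == -1).mean(axis=0)
    p_plus = (chain.w == 1).mean(axis=0)
    p_zero = 1.0 - p_minus - p_plus
    bfs = np.array([
        snp_bf(chain, prior, nsg, int(snp_gene[j]), j)
        for j in range(chain.n_snps)
    ])
    snp_table = pd.DataFrame({
        "snp": data.snp_labels,
        "gene": [data.gene_labels[g] for g in snp_gene],
        "p_minus": p_minus, "p_zero": p_zero, "p_plus": p_plus,
        "bf": bfs, "grade": [evidence_grade(v) for v in bfs],
    })

    included = chain.w != 0                      # (scans, snps)
    gene_in = np.zeros((n_scans, data.n_genes), dtype=bool)
    np.logical_or.at(gene_in.T, snp_gene, included.T)
    gbfs = np.array([
        gene_bf(chain, prior, nsg, snp_gene, g) for g in range(data.n_genes)
    ])
    mean_snps_in = np.zeros(data.n_genes)
    np.add.at(mean_snps_in, snp_gene, included.mean(axis=0))
    gene_table = pd.DataFrame({
        "gene": data.gene_labels,
        "n_snps": nsg,
        "p_included": gene_in.mean(axis=0),
        "bf": gbfs, "grade": [evidence_grade(v) for v in gbfs],
        "beta_mean": chain.beta.mean(axis=0),
        "beta_sd": chain.beta.std(axis=0, ddof=1) if n_scans > 1
        else np.zeros(data.n_genes),
        "mean_snps_included": mean_snps_in,
    })

    rows = []
    def add_param(name, draws):
        draws = np.atleast_2d(draws.T).T
        for k in range(draws.shape[1]):
            label = name if draws.shape[1] == 1 else f"{name}_{k}"
            col = draws[:, k]
            rows.append({"parameter": label, "mean": col.mean(),
                         "sd": col.std(ddof=1) if n_scans > 1 else 0.0})
    add_param("alpha", chain.alpha) if chain.alpha.shape[1] else None
    add_param("pi", chain.pi)
    add_param("sigma2", chain.sigma2[:, None])
    add_param("tau2", chain.tau2[:, None])
    sp = np.array([spatiality(s, t)
                   for s, t in zip(chain.sigma2, chain.tau2)])
    add_param("spatiality", sp[:, None])
    params = pd.DataFrame(rows)

    def count_dist(counts):
        vals, freq = np.unique(counts, return_counts=True)
        return pd.DataFrame({"count": vals, "probability": freq / n_scans})

    return SummaryTables(
        snp_table=snp_table, gene_table=gene_table, params=params,
        snp_count_dist=count_dist(included.sum(axis=1)),
        gene_count_dist=count_dist(gene_in.sum(axis=1)),
    )
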