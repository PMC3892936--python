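import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from snpburden.core_types import (AnnotationMatrix, HyperParams, ModelState,
                                  PriorSpec, StudyData)


@pytest.fixture
def tiny_study():
    """3 subjects in 1 risk set (1 case + 2 controls), 2 SNPs in 1 gene."""
    return StudyData(
        y=[1, 0, 0],
        x=np.zeros((3, 0)),
        genotypes=[[2, 1], [0, 1], [1, 0]],
        snp_gene=[0, 0],
        riskset=[0, 0, 0],
        offset=[0.0, 0.0, 0.0],
    )


def random_study(rng, n_sets=12, n_genes=2, snps_per_gene=(2, 3), set_size=2,
                 n_cov=0, maf=0.3):
    """Small random matched study used across unit tests."""
    snps = int(np.sum(snps_per_gene))
    n = n_sets * set_size
    geno = rng.binomial(2, maf, size=(n, snps)).astype(np.int8)
    y = np.zeros(n, dtype=np.int8)
    riskset = np.repeat(np.arange(n_sets), set_size)
    for r in range(n_sets):
        y[r * set_size + rng.integers(set_size)] = 1
    x = rng.standard_normal((n, n_cov)) if n_cov else np.zeros((n, 0))
    return StudyData(
        y=y, x=x, genotypes=geno,
        snp_gene=np.repeat(np.arange(n_genes), snps_per_gene),
        riskset=riskset, offset=np.zeros(n),
    )


def simple_prior(n_genes=2, phi=0.05, nbar=2.5, c=1.0, scaling="eq5",
                 n_z=0, a=None):
    z = np.column_stack([np.ones(n_genes)]
                        + [np.linspace(0, 1, n_genes)] * n_z)
    if a is None:
        a = np.eye(n_genes)
    return PriorSpec(phi_plus=phi, phi_minus=phi, c=c, nbar=nbar, z=z, a=a,
                     hyper=HyperParams(), scaling=scaling)


def null_state(n_snps, n_genes, n_pi=1, n_alpha=0):
    return ModelState(
        w=np.zeros(n_snps, dtype=np.int8), beta=np.zeros(n_genes),
        b=np.zeros(n_genes), pi=np.zeros(n_pi), alpha=np.zeros(n_alpha),
        sigma2=0.25, tau2=0.25, vpi=1.0,
    )
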