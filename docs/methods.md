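# Methods

## Model

`snpburden` fits a three-level Bayesian hierarchical model relating SNPs
grouped into candidate genes to a binary outcome in matched case-control
data.

**Level 1 (subjects).** Each gene g contributes through a signed burden
index

    G_ig = sum_s W_gs * S_igs,        W_gs in {-1, 0, +1},

where S_igs is the additive minor-allele count (0/1/2).  The linear
predictor is

    eta_i = X_i' alpha + sum_g exp(beta_g) * G_ig + offset_i        (Model I)

and inference uses the conditional logistic likelihood over matched risk
sets: each set (one case, one or more controls) contributes
`eta_case - log sum_j exp(eta_j)`.  Conditioning removes per-set nuisance
intercepts, so offsets and covariates matter only through within-set
contrasts.  The per-subject `offset` column exists to carry log
sampling-weight corrections for counter-matched designs; the package treats
it as a supplied number and does not derive it.  Exponentiating beta_g keeps
every gene's coefficient positive, which removes the label-switching
symmetry between (beta_g, W_g) and (beta_g, -W_g): flipping all weight signs
in a gene genuinely changes the likelihood (this is asserted in the test
suite).

**Level 2 (genes).**  beta_g = Z_g' pi + b_g + e_g with
pi ~ N(0, V_pi I), b ~ MVN(0, tau^2 A), e ~ N(0, sigma^2 I).  Z is a
gene-by-term binary design matrix (intercept first) built from a selected
subset of ontology terms; A is the Pearson correlation matrix of the genes'
full binary annotation rows.  tau^2 measures how much residual gene-level
variance is carried by the ontology similarity structure; the ratio
tau^2/(sigma^2 + tau^2) ("spatiality") summarizes that partition.

**Level 3 (SNPs).**  Weights have prior
Pr(W_gs = d) = phi_d * (Nbar + c)/(N_Sg + c) for d = -1, +1, remainder on
d = 0, where N_Sg is the gene's SNP count, Nbar the study average and c a
small-count stabilizer (by convention the minimum SNP count over genes).
Scaling by gene size keeps the expected number of selected SNPs roughly
constant across genes.  Variances get conjugate inverse-gamma hyperpriors
sigma^2 ~ IG(df_e, E), tau^2 ~ IG(df_b, B), V_pi ~ IG(1, P), in shape/scale
parameterization p(x) ∝ x^{-df-1} e^{-scale/x}.

**Model II** replaces exp(beta_g) with a linear coefficient beta_g >= 0
under a point-mass-plus-truncated-normal prior: density
phi((beta_g - Z_g'pi)/sigma)/sigma on beta_g > 0 and a point mass
Phi(-Z_g'pi/sigma) at zero.  Because the point mass breaks the level-2
Gaussian structure, Model II has no correlated effect b (it is held at 0 and
tau^2 is not updated) and pi and sigma^2 are updated by Metropolis-Hastings
rather than Gibbs.

## Prior-scaling conventions

The size-balanced weight prior and the Bayes-factor prior odds must use the
same per-SNP inclusion probability, otherwise a chain that exactly
reproduces its prior would not give BF = 1.  Two conventions are offered:

* `eq5` (default): p_d = phi_d (Nbar + c)/(N_Sg + c);
* `eq7_literal`: p_d = phi_d/(N_Sg + c).

The configured convention is applied consistently to truth simulation, the
sampling prior and the prior odds of both SNP- and gene-level Bayes
factors.  Under `eq5`, very small genes can receive scaled inclusion mass
above 1; the mass p_- + p_+ is therefore capped (default 0.5, shrinking
both sides proportionally, with a warning).  At the default settings
(phi = 0.05 each, c = 1) the `eq5` convention yields about 48 expected
causal SNPs out of 504 and `eq7_literal` about 3.5; both are documented
rather than calibrated to any external count.

## MCMC

One scan updates, in order:

1. **W** — every SNP in a freshly randomized order is redrawn from its
   exact three-way full conditional Pr(d) ∝ prior_d * L(W_gs = d), with all
   other parameters fixed.  The likelihood change is computed incrementally:
   for each SNP only risk sets containing a carrier are touched, with
   per-SNP member indices precomputed once per fit, and the per-set
   log-sum-exp cache is updated in place on acceptance.  The incremental
   deltas agree with full recomputation to 1e-10 (tested).
2. **beta** — a multivariate normal random-walk MH move of the whole beta
   vector against the conditional logistic likelihood plus its
   N(Z'pi + b, sigma^2) prior.
3. **b** — an exact Gibbs draw.  b enters the likelihood only through the
   level-2 residual of beta, so its full conditional is Gaussian with
   precision A^{-1}/tau^2 + I/sigma^2.  Sampling it exactly (rather than by
   a joint MH move with beta) removes the slow random walk along the
   beta-b-pi ridge that otherwise dominates mixing in the weak-data regime.
4. **pi** — exact conjugate Gibbs (the level-2 model is linear-Gaussian):
   precision Z'Z/sigma^2 + I/V_pi.  A random-walk MH fallback
   (`pi_update="mh"`) targets the same conditional.
5. **sigma^2, tau^2, V_pi** — conjugate inverse-gamma Gibbs draws.
6. **alpha** — random-walk MH against the conditional likelihood under a
   flat prior.

Proposal scales adapt by Robbins-Monro toward 0.3 acceptance during burn-in
only and are frozen afterwards, preserving detailed balance for the
retained scans.  All randomness flows through one seeded generator;
identical seeds give bit-identical chains.

Initialization: W = 0, pi = 0, beta = 0, b = 0, alpha from one Newton step
of the conditional logistic score at zero, sigma^2 = tau^2 = 0.25,
V_pi = 1.  The null start avoids pathological initial likelihoods; a
dispersed-start agreement check is part of the test suite.

Default chain length is 1000 retained scans after 500 burn-in, the
reference operating settings; convergence-sensitive analyses should scale
these up (the prior-recovery tests use 60-fold thinning, for example).

## Posterior summaries

Inclusion probabilities are scan frequencies.  Bayes factors divide
posterior odds by prior odds; a 0.5 pseudo-count is added to both the
inclusion and exclusion scan counts so chains that never (or always)
include a SNP still produce finite BFs.  The gene-level event is "at least
one SNP of the gene included", with prior probability
1 - (1 - p_incl)^{N_Sg}.  When the prior puts zero mass on inclusion
(phi = 0) the BF is undefined and reported as NaN.  Evidence grades use the
conventional strict thresholds 3 (positive), 20 (strong), 150 (very
strong).  A Rao-Blackwellized alternative to the frequency estimator was
considered and rejected for the default because the frequency estimator is
the one the tabulation definitions imply; the pseudo-count policy is this
package's own choice where the source material is silent.

## Synthetic data generator

The generator emulates the structure of a candidate-gene study of DNA
damage response and second breast cancers: 38 genes with a fixed SNP-count
vector (1 to 51 per gene, 504 total, mean 13.3), 860 binary ontology-like
terms, and 700 matched risk sets, 70% of size 2 and 30% of size 3 (echoing
a 708-case / 1401-control design).  Defaults follow the reference
simulation settings: second-level effects pi = (-2, 0.25, 0.5, 0.75, 1)
(intercept first, then four designated terms), sigma = tau = 0.5,
phi = 0.05 each, c = 1.

Annotations are block-structured: genes are assigned to 8 simulated
pathways and non-reserved terms are block-specific (membership probability
0.75 within the block, 0.02 outside), so derived similarities span roughly
0 to 0.8 as in real ontology profiles; four reserved terms (annotated to
about a quarter of genes each) serve as the Z covariates.  Genotypes are
independent Hardy-Weinberg draws at per-SNP minor-allele frequencies
uniform on (0.05, 0.5).  Covariates default to one standard-normal column
with alpha = 0.5, and offsets to zero.  Case status is assigned within each
risk set with probability proportional to exp(eta).

What the generator does *not* emulate: linkage disequilibrium between SNPs,
real covariate distributions, counter-matching offsets, or the real
genotype matrix of any study.  Passing operating-characteristic checks on
this generator therefore demonstrates correct inference under the model's
own assumptions with realistic dimensions, not performance on real LD
structure.

## Replicated operating-characteristics study

`run_simulation_study` draws truth realizations (annotations, beta, W),
generates replicate datasets per truth, fits each and aggregates by
true-weight class: average posterior Pr(W = -1/0/+1) as row percentages and
the share of SNPs/genes exceeding BF 3/20/150.  The acceptance script runs
3 truths x 3 replicates at 350 risk sets with 1000 retained scans after 500
burn-in — dimensions chosen so a complete run takes a few minutes on one
core while leaving hundreds of null SNPs and dozens of genes per class.
Full-scale replication (10 x 10 at 700 sets) is a matter of changing two
arguments.

## Numerical choices and edge cases

* All set-level reductions use pairwise `logaddexp`; raw exponentials of
  eta are never formed.
* A is symmetrized, and repaired to positive definite by doubling diagonal
  jitter from 1e-8 until the smallest eigenvalue exceeds 1e-10, then
  rescaled to unit diagonal; the applied jitter is logged.  Jitter repair
  preserves off-diagonal structure, unlike nearest-PD projection.
* Genes whose annotation row is constant are rejected under the correlation
  similarity (undefined); the Jaccard alternative accepts them.
* Missing genotypes impute to 0 (reference) by default, or to the rounded
  per-SNP mean (`missing_policy="mean"`).
* Model II proposals below zero are rejected outright; the birth/death move
  pairs a half-normal birth proposal with a 50% death probability, with the
  exact Hastings correction.
* SNPs with no carriers have a flat likelihood and are sampled from their
  prior.

## Known limitations

* The W update holds beta fixed within a scan; weights and coefficients are
  not proposed jointly, so very strong posterior coupling between a gene's
  beta and its weight vector can slow mixing.
* Model II's pi/sigma^2 MH updates are serviceable but less efficient than
  the Model I Gibbs path.
* No G-by-E interaction terms, no SNP-level prior covariates, and no
  analytic (non-MCMC) approximation for biobank-scale data.
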