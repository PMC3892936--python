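"""Data model, validation and file I/O for matched case-control SNP-set studies.

The central container is :class:`StudyData`: genotypes for ``N_I`` subjects at
SNPs grouped into genes, a binary outcome, matched risk-set labels, fixed
covariates and a per-subject offset (used to absorb counter-matching sampling
weights).  :class:`AnnotationMatrix` holds the binary gene-by-term ontology
table from which the prior design matrix Z and the gene-gene similarity
matrix A are derived.  :class:`ModelState` and :class:`ChainSamples` carry the
latent parameters of the hierarchical model at one MCMC scan and across
retained scans, respectively.

All external files are plain TSV; see the reader docstrings for the expected
columns.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StudyData",
    "AnnotationMatrix",
    "ModelState",
    "PriorSpec",
    "HyperParams",
    "ChainSamples",
    "StudyValidationError",
    "StudyParseError",
    "load_study",
    "load_annotations",
    "write_chain",
    "read_chain",
]


class StudyParseError(ValueError):
    """A study input file could not be parsed."""


class StudyValidationError(ValueError):
    """Parsed study inputs violate a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """Subjects, genotypes, risk sets, covariates and offsets.

    Attributes
    ----------
    y : (N_I,) int array of 0/1 outcomes; exactly one 1 per risk set.
    x : (N_I, p) float array of fixed covariates (may have p == 0).
    genotypes : (N_I, N_S) int array with additive minor-allele counts 0/1/2.
    snp_gene : (N_S,) int array mapping each SNP to a gene index in
        ``0..n_genes-1``.
    riskset : (N_I,) int array of risk-set codes in ``0..n_risksets-1``.
    offset : (N_I,) float array of per-subject log sampling-weight offsets.
    """

    y: np.ndarray
    x: np.ndarray
    genotypes: np.ndarray
    snp_gene: np.ndarray
    riskset: np.ndarray
    offset: np.ndarray
    subject_ids: list = field(default_factory=list)
    snp_labels: list = field(default_factory=list)
    gene_labels: list = field(default_factory=list)
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            self.x = self.x.reshape(self.y.shape[0], -1)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.snp_gene = np.asarray(self.snp_gene, dtype=np.intp)
        self.riskset = np.asarray(self.riskset, dtype=np.intp)
        self.offset = np.asarray(self.offset, dtype=float)
        if not self.subject_ids:
            self.subject_ids = [f"subj{i+1}" for i in range(self.n_subjects)]
        if not self.snp_labels:
            self.snp_labels = [f"snp{i+1}" for i in range(self.n_snps)]
        if not self.gene_labels:
            self.gene_labels = [f"gene{i+1}" for i in range(self.n_genes)]
        if not self.covariate_names:
            self.covariate_names = [f"x{i+1}" for i in range(self.x.shape[1])]
        self.validate()

    # -- shape helpers -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_genes(self) -> int:
        return int(self.snp_gene.max()) + 1 if self.snp_gene.size else 0

    @property
    def n_risksets(self) -> int:
        return int(self.riskset.max()) + 1 if self.riskset.size else 0

    @property
    def snps_per_gene(self) -> np.ndarray:
        """(n_genes,) array of N_S_g, the SNP count per gene."""
        return np.bincount(self.snp_gene, minlength=self.n_genes)

    def validate(self) -> None:
        if self.genotypes.shape[0] != self.n_subjects:
            raise StudyValidationError("genotype rows do not match subjects")
        if self.snp_gene.shape[0] != self.n_snps:
            raise StudyValidationError("snp_gene length does not match SNP count")
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            i, j = (int(v) for v in np.argwhere(bad)[0])
            raise StudyValidationError(
                f"genotype value {self.genotypes[i, j]} for subject "
                f"{self.subject_ids[i]} SNP {self.snp_labels[j]} not in {{0,1,2}}"
            )
        if self.snp_gene.size and (self.snps_per_gene == 0).any():
            g = int(np.flatnonzero(self.snps_per_gene == 0)[0])
            raise StudyValidationError(f"gene {self.gene_labels[g]} has no SNPs")
        # exactly one case per matched set
        cases = np.bincount(self.riskset, weights=self.y, minlength=self.n_risksets)
        sizes = np.bincount(self.riskset, minlength=self.n_risksets)
        if (sizes < 2).any():
            r = int(np.flatnonzero(sizes < 2)[0])
            raise StudyValidationError(f"risk set {r} has fewer than 2 members")
        if (cases != 1).any():
            r = int(np.flatnonzero(cases != 1)[0])
            raise StudyValidationError(
                f"risk set {r} contains {int(cases[r])} cases (exactly 1 required)"
            )


@dataclass
class AnnotationMatrix:
    """Binary gene-by-term ontology membership table."""

    genes: list
    terms: list
    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.int8)
        if self.m.shape != (len(self.genes), len(self.terms)):
            raise StudyValidationError("annotation matrix shape mismatch")
        if not np.isin(self.m, (0, 1)).all():
            raise StudyParseError("annotation entries must be 0/1")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass
class HyperParams:
    """Inverse-gamma hyperprior constants: sigma2~IG(df_e,E), tau2~IG(df_b,B),
    Vpi~IG(1,P) (shape/scale parameterization)."""

    df_e: float = 3.0
    e: float = 1.0
    df_b: float = 3.0
    b: float = 1.0
    p: float = 1.0


@dataclass
class PriorSpec:
    """Everything the prior needs: weight-assignment parameters phi_+/phi_-,
    the small-count stabilizer c, the average SNPs per gene N-bar, the prior
    design matrix Z (intercept first), the gene-gene similarity matrix A and
    the variance hyperparameters.

    ``scaling`` selects the per-SNP prior-probability convention; "eq5"
    multiplies phi_d by (Nbar + c)/(N_S_g + c) while "eq7_literal" uses
    phi_d/(N_S_g + c).  The same convention feeds sampling and Bayes-factor
    prior odds so that BF = 1 exactly when posterior equals prior.
    """

    phi_plus: float
    phi_minus: float
    c: float
    nbar: float
    z: np.ndarray
    a: np.ndarray
    hyper: HyperParams = field(default_factory=HyperParams)
    scaling: str = "eq5"

    def __post_init__(self):
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.a = np.asarray(self.a, dtype=float)
        if self.phi_plus < 0 or self.phi_minus < 0:
            raise ValueError("phi parameters must be nonnegative")
        if self.phi_plus + self.phi_minus >= 1:
            raise ValueError("phi_plus + phi_minus must be < 1")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.scaling not in ("eq5", "eq7_literal"):
            raise ValueError(f"unknown prior scaling {self.scaling!r}")

    @property
    def n_genes(self) -> int:
        return self.z.shape[0]


@dataclass
class ModelState:
    """All latent parameters at one MCMC scan.

    w is the per-SNP weight in {-1, 0, +1}; beta the per-gene burden
    coefficient (entering the linear predictor as exp(beta) under Model I and
    as beta >= 0 under Model II); b the correlated gene random effect; pi the
    second-level coefficients (intercept first); alpha the fixed-covariate
    coefficients; sigma2/tau2/vpi the independent, correlated and
    second-level prior variances.
    """

    w: np.ndarray
    beta: np.ndarray
    b: np.ndarray
    pi: np.ndarray
    alpha: np.ndarray
    sigma2: float
    tau2: float
    vpi: float

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.int8)
        self.beta = np.asarray(self.beta, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.isin(self.w, (-1, 0, 1)).all():
            raise ValueError("weights must lie in {-1, 0, +1}")
        for name in ("sigma2", "tau2", "vpi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def copy(self) -> "ModelState":
        return replace(
            self,
            w=self.w.copy(),
            beta=self.beta.copy(),
            b=self.b.copy(),
            pi=self.pi.copy(),
            alpha=self.alpha.copy(),
        )


@dataclass
class ChainSamples:
    """Retained post-burn-in scans.

    Arrays are indexed scan-first: ``w`` is (n_keep, N_S) int8, ``beta``/``b``
    are (n_keep, N_G), ``pi`` is (n_keep, 1+N_Z), ``alpha`` (n_keep, p) and the
    variances are (n_keep,).  ``meta`` records seed, burn-in, thinning and the
    model variant.
    """

    w: np.ndarray
    beta: np.ndarray
    b: np.ndarray
    pi: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    tau2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.int8)
        for name in ("beta", "b", "pi", "alpha", "sigma2", "tau2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.w.shape[0]
        for name in ("beta", "b", "pi", "alpha", "sigma2", "tau2"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"chain block {name} has inconsistent length")

    @property
    def n_scans(self) -> int:
        return self.w.shape[0]

    @property
    def n_snps(self) -> int:
        return self.w.shape[1]

    @property
    def n_genes(self) -> int:
        return self.beta.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           na_values=["NA", ""])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise StudyParseError(f"could not read {path}: {exc}") from exc


def load_study(genotype_path, subject_path, snp_map_path,
               missing_policy: str = "zero") -> StudyData:
    """Read genotype, subject and SNP-map TSVs into a validated StudyData.

    Genotype file: rows = subjects (first column ``subject_id``), columns =
    SNP labels, entries 0/1/2 or NA.  Subject file: columns ``subject_id``,
    ``riskset_id``, ``case``, ``offset`` then covariates.  SNP map: columns
    ``snp_id``, ``gene_id``.

    ``missing_policy`` resolves NA genotypes: "zero" imputes the reference
    genotype 0; "mean" imputes the per-SNP mean count rounded to the nearest
    integer.
    """
    if missing_policy not in ("zero", "mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    geno_df = _read_tsv(genotype_path)
    subj_df = _read_tsv(subject_path)
    map_df = _read_tsv(snp_map_path)

    for col in ("subject_id", "riskset_id", "case", "offset"):
        if col not in subj_df.columns:
            raise StudyParseError(f"subject file lacks column {col!r}")
    for col in ("snp_id", "gene_id"):
        if col not in map_df.columns:
            raise StudyParseError(f"snp map lacks column {col!r}")
    if geno_df.columns[0] != "subject_id":
        raise StudyParseError("genotype file must start with a subject_id column")

    snp_labels = list(geno_df.columns[1:])
    snp_to_gene = dict(zip(map_df["snp_id"], map_df["gene_id"]))
    missing_map = [s for s in snp_labels if s not in snp_to_gene]
    if missing_map:
        raise StudyValidationError(
            f"SNPs absent from snp map: {', '.join(missing_map[:5])}"
        )
    gene_labels = list(dict.fromkeys(snp_to_gene[s] for s in snp_labels))
    gene_index = {g: i for i, g in enumerate(gene_labels)}
    snp_gene = np.array([gene_index[snp_to_gene[s]] for s in snp_labels])

    # align subjects; reject subjects without a risk set
    if subj_df["riskset_id"].isna().any():
        bad = subj_df.loc[subj_df["riskset_id"].isna(), "subject_id"].iloc[0]
        raise StudyValidationError(f"subject {bad} has no risk set")
    order = {s: i for i, s in enumerate(subj_df["subject_id"])}
    unknown = [s for s in geno_df["subject_id"] if s not in order]
    if unknown:
        raise StudyValidationError(f"genotyped subject {unknown[0]} not in subject file")
    geno_df = geno_df.set_index("subject_id").loc[list(subj_df["subject_id"])]

    raw = geno_df.to_numpy()
    geno = np.zeros(raw.shape, dtype=float)
    missing = np.zeros(raw.shape, dtype=bool)
    for (i, j), val in np.ndenumerate(raw):
        if val is None or (isinstance(val, float) and np.isnan(val)):
            missing[i, j] = True
            continue
        try:
            x = float(val)
        except (TypeError, ValueError):
            raise StudyParseError(
                f"genotype row {i + 2}: value {val!r} is not numeric"
            ) from None
        if x not in (0.0, 1.0, 2.0):
            raise StudyParseError(f"genotype row {i + 2}: value {val!r} not in {{0,1,2}}")
        geno[i, j] = x
    if missing.any():
        if missing_policy == "zero":
            geno[missing] = 0
        else:
            col_mean = np.where(
                missing.all(axis=0), 0.0,
                np.nansum(np.where(missing, np.nan, geno), axis=0)
                / np.maximum((~missing).sum(axis=0), 1),
            )
            fill = np.clip(np.rint(col_mean), 0, 2)
            geno[missing] = np.broadcast_to(fill, geno.shape)[missing]

    try:
        y = subj_df["case"].astype(int).to_numpy()
        offset = subj_df["offset"].astype(float).to_numpy()
    except ValueError as exc:
        raise StudyParseError(f"subject file: {exc}") from exc
    if not np.isin(y, (0, 1)).all():
        raise StudyParseError("case column must be 0/1")

    riskset_labels = list(dict.fromkeys(subj_df["riskset_id"]))
    rs_index = {r: i for i, r in enumerate(riskset_labels)}
    riskset = np.array([rs_index[r] for r in subj_df["riskset_id"]])

    cov_cols = [c for c in subj_df.columns
                if c not in ("subject_id", "riskset_id", "case", "offset")]
    try:
        x = subj_df[cov_cols].astype(float).to_numpy() if cov_cols else \
            np.zeros((len(subj_df), 0))
    except ValueError as exc:
        raise StudyParseError(f"covariate column not numeric: {exc}") from exc

    return StudyData(
        y=y, x=x, genotypes=geno.astype(np.int8), snp_gene=snp_gene,
        riskset=riskset, offset=offset,
        subject_ids=list(subj_df["subject_id"]), snp_labels=snp_labels,
        gene_labels=gene_labels, covariate_names=cov_cols,
    )


def load_annotations(path, allow_empty_genes: bool = False) -> AnnotationMatrix:
    """Read a gene-by-term TSV of 0/1 memberships (first column ``gene_id``).

    Duplicate term columns are dropped (first kept).  Constant columns are
    uninformative for similarity and trigger a warning.  A gene annotated to
    no term makes its similarity to other genes undefined and is rejected
    unless ``allow_empty_genes``.
    """
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise StudyParseError("annotation file must start with a gene_id column")
    genes = list(df["gene_id"])
    df = df.drop(columns="gene_id")
    dup = df.columns.duplicated()
    if dup.any():
        df = df.loc[:, ~dup]
    vals = df.to_numpy()
    for (i, j), v in np.ndenumerate(vals):
        if str(v) not in ("0", "1"):
            raise StudyParseError(
                f"annotation row {i + 2}, term {df.columns[j]!r}: "
                f"entry {v!r} is not 0/1"
            )
    m = vals.astype(np.int8)
    const = (m == m[0]).all(axis=0)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant (uninformative) annotation term(s)",
            stacklevel=2,
        )
    empty = m.sum(axis=1) == 0
    if empty.any() and not allow_empty_genes:
        raise StudyValidationError(
            f"gene {genes[int(np.flatnonzero(empty)[0])]} has no annotations "
            "(pass allow_empty_genes=True to override)"
        )
    return AnnotationMatrix(genes=genes, terms=list(df.columns), m=m)


_CHAIN_FMT = "%.17g"


def write_chain(chain: ChainSamples, path) -> None:
    """Write retained scans to a single TSV (one row per scan).

    Header comments record metadata as JSON; columns are ``scan`` then
    ``W_<j>``, ``beta_<g>``, ``b_<g>``, ``pi_<k>``, ``alpha_<k>``, ``sigma2``,
    ``tau2``.  The round-trip through :func:`read_chain` is lossless.
    """
    if chain.n_scans == 0:
        raise ValueError("refusing to write an empty chain")
    blocks = {"beta": chain.beta, "b": chain.b, "pi": chain.pi,
              "alpha": chain.alpha, "sigma2": chain.sigma2, "tau2": chain.tau2}
    for name, arr in blocks.items():
        if not np.isfinite(arr).all():
            raise ValueError(f"chain block {name} contains non-finite values")
    cols = ["scan"]
    cols += [f"W_{j+1}" for j in range(chain.n_snps)]
    cols += [f"beta_{g+1}" for g in range(chain.n_genes)]
    cols += [f"b_{g+1}" for g in range(chain.n_genes)]
    cols += [f"pi_{k}" for k in range(chain.pi.shape[1])]
    cols += [f"alpha_{k+1}" for k in range(chain.alpha.shape[1])]
    cols += ["sigma2", "tau2"]
    with open(path, "w") as fh:
        fh.write("# snpburden chain v1\n")
        fh.write("# meta: " + json.dumps(chain.meta, sort_keys=True) + "\n")
        fh.write("\t".join(cols) + "\n")
        for t in range(chain.n_scans):
            row = [str(t)]
            row += [str(int(v)) for v in chain.w[t]]
            row += [_CHAIN_FMT % v for v in chain.beta[t]]
            row += [_CHAIN_FMT % v for v in chain.b[t]]
            row += [_CHAIN_FMT % v for v in chain.pi[t]]
            row += [_CHAIN_FMT % v for v in chain.alpha[t]]
            row += [_CHAIN_FMT % chain.sigma2[t], _CHAIN_FMT % chain.tau2[t]]
            fh.write("\t".join(row) + "\n")


def read_chain(path) -> ChainSamples:
    """Read a chain written by :func:`write_chain`."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# snpburden chain"):
        raise StudyParseError(f"{path}: not a snpburden chain file")
    meta = {}
    body_start = 1
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("# meta: "):
            meta = json.loads(line[len("# meta: "):])
        elif not line.startswith("#"):
            body_start = i
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t",
                     float_precision="round_trip")
    try:
        pick = lambda pre: df[[c for c in df.columns if c.startswith(pre)]].to_numpy()
        chain = ChainSamples(
            w=pick("W_"), beta=pick("beta_"), b=pick("b_"), pi=pick("pi_"),
            alpha=pick("alpha_"), sigma2=df["sigma2"].to_numpy(),
            tau2=df["tau2"].to_numpy(), meta=meta,
        )
    except (KeyError, ValueError) as exc:
        raise StudyParseError(f"{path}: corrupt chain record ({exc})") from exc
    return chain
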