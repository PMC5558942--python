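"""Bayesian phylogenetic generalized linear mixed model (PGLMM).

The cross-species model treats every individual record as one observation
of standardized body mass and asks whether mass declines with year of
collection once geography, sex and phylogeny are accounted for:

    z_ij = x_ij' beta + u_{s(i)} + e_ij,
    u ~ N(0, sigma_a^2 A),   e_ij ~ N(0, sigma_e^2),

where ``A`` is the phylogenetic relatedness matrix — A[i, j] is the branch
length shared by the root-to-tip paths of species i and j (shared-branch
counts when all branch lengths are 1). Fixed effects are year of
collection, taxonomic class, habitat, absolute latitude, longitude, sex
and series length, optionally with a year x class or year x habitat
interaction.

Inference is by a conjugate Gibbs sampler: the stacked fixed and species
effects are drawn jointly from their Gaussian full conditional (the
mixed-model equations), and the two variance components from their
inverse-gamma full conditionals. Priors are near-flat Gaussians for the
fixed effects and inverse-Wishart (univariate: inverse-gamma with shape
nu/2 and scale nu*V/2) for the variances, with scale V equal to half the
response variance and nu = 3 degrees of freedom. Coefficients are
summarized by posterior means, equal-tailed 95% credible intervals and
pMCMC — twice the proportion of retained draws on the opposite side of
zero, floored at one over the retained-sample count — and model fit by
the deviance information criterion (DIC), conditional on the species
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .records import RecordTable, SpeciesMeta

__all__ = [
    "PhyloCovariance", "phylo_covariance", "standardize_mass",
    "PriorSpec", "ChainConfig", "PosteriorChain", "PhylogeneticGLMM",
    "pmcmc", "coefficient_contrast", "ContrastResult",
]


# ---------------------------------------------------------------------------
# phylogenetic covariance

@dataclass
class PhyloCovariance:
    """Shared-ancestry covariance over an ordered species list."""

    species: list
    matrix: np.ndarray
    scaling: str  # "raw" | "unit_diagonal"

    def reorder(self, species_order) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in species_order]
        return PhyloCovariance(list(species_order),
                               self.matrix[np.ix_(idx, idx)], self.scaling)


def phylo_covariance(tree: dendropy.Tree, scaling: str = "unit_diagonal",
                     species_order=None,
                     default_branch_length: float = 1.0) -> PhyloCovariance:
    """Relatedness matrix A from a rooted tree.

    ``A[i, j]`` is the root-to-MRCA distance of tips i and j (the branch
    length their root paths share); ``A[i, i]`` is the tip's root
    distance. ``scaling="unit_diagonal"`` rescales to
    ``A[i,j]/sqrt(A[i,i] A[j,j])`` so the diagonal is exactly 1.
    """
    if scaling not in ("raw", "unit_diagonal"):
        raise ValueError(f"unknown scaling {scaling!r}")
    root = tree.seed_node
    depth = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length if node.edge.length is not None else default_branch_length
        depth[node] = depth[node.parent_node] + bl

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    pos = {lf: i for i, lf in enumerate(leaves)}
    m = len(leaves)
    A = np.zeros((m, m))
    for lf in leaves:
        A[pos[lf], pos[lf]] = depth[lf]
    # MRCA depth for every pair: at each internal node, pairs of leaves in
    # different child subtrees have that node as their MRCA
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = [pos[node]]
            continue
        kids = [leafsets[c] for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        A[i, j] = A[j, i] = depth[node]
        leafsets[node] = [i for k in kids for i in k]

    if scaling == "unit_diagonal":
        d = np.diag(A)
        if np.any(d <= 0):
            bad = [labels[i] for i in np.where(d <= 0)[0]]
            raise ValueError(f"zero-depth tips, cannot unit-scale: {bad}")
        A = A / np.sqrt(np.outer(d, d))

    cov = PhyloCovariance(labels, A, scaling)
    if species_order is not None:
        missing = [s for s in species_order if s not in labels]
        if missing:
            raise ValueError(f"species not in tree: {missing}")
        cov = cov.reorder(list(species_order))
    return cov


# ---------------------------------------------------------------------------
# response standardization

def standardize_mass(records: RecordTable, scope: str = "within_species") -> pd.Series:
    """Z-score body mass (sample sd), per species or over the pooled table.

    Within-species scoping removes the several-orders-of-magnitude
    allometric spread so that the species intercepts and habitat terms act
    on relative size.
    """
    df = records.df
    if scope == "within_species":
        sd = df.groupby("species_id")["mass"].transform("std")
        if (sd == 0).any() or sd.isna().any():
            bad = sorted(df.loc[(sd == 0) | sd.isna(), "species_id"].unique())
            raise ValueError(f"zero-variance mass for species: {bad}")
        mu = df.groupby("species_id")["mass"].transform("mean")
        return (df["mass"] - mu) / sd
    if scope == "global":
        sd = df["mass"].std()
        if not sd > 0:
            raise ValueError("zero-variance mass")
        return (df["mass"] - df["mass"].mean()) / sd
    if scope == "none":
        return df["mass"].astype(float)
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# priors, chain configuration, posterior container

@dataclass
class PriorSpec:
    """Priors for the PGLMM.

    v_fix : prior variance of each fixed effect (near-flat Gaussian).
    nu, scale : inverse-gamma shape nu/2 and scale nu*scale/2 for both
        variance components; ``scale=None`` means var(response)/2.
    fixed_phylo_variance : pin sigma_a^2 at a constant instead of
        sampling it (a degenerate prior; useful for reducing the model to
        ordinary regression).
    """

    v_fix: float = 1e8
    nu: float = 3.0
    scale: float | None = None
    fixed_phylo_variance: float | None = None

    def __post_init__(self):
        if self.v_fix <= 0 or self.nu <= 0:
            raise ValueError("v_fix and nu must be positive")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("prior scale must be positive")


@dataclass
class ChainConfig:
    """MCMC run lengths. Defaults retain (250000-50000)/100 = 2000 draws."""

    total: int = 250_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self):
        kept = self.total - self.burn_in
        if kept <= 0 or kept % self.thin:
            raise ValueError(
                "(total - burn_in) must be a positive multiple of thin")

    @property
    def retained(self) -> int:
        return (self.total - self.burn_in) // self.thin


def pmcmc(draws) -> float:
    """Twice the minority-sign fraction of draws, floored at 1/n.

    ``p = max(1/n, 2 * min(#{d > 0}, #{d < 0}) / n)``. All-zero draws are
    degenerate: NaN with a warning.
    """
    d = np.asarray(draws, float)
    n = d.size
    if n < 1:
        raise ValueError("need at least one draw")
    npos = int(np.count_nonzero(d > 0))
    nneg = int(np.count_nonzero(d < 0))
    if npos == 0 and nneg == 0:
        warnings.warn("all draws are exactly zero; pMCMC undefined",
                      stacklevel=2)
        return float("nan")
    return max(1.0 / n, 2.0 * min(npos, nneg) / n)


def _ess(x: np.ndarray) -> float:
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(x)[None, :]))


@dataclass
class PosteriorChain:
    """Retained draws of all coefficients and variance components."""

    coef_names: list
    draws: pd.DataFrame           # retained x (coefs + sigma_a2 + sigma_e2)
    deviance: np.ndarray
    dic: float
    p_d: float
    config: ChainConfig
    species: list = field(default_factory=list)
    species_effects: pd.DataFrame | None = None

    @property
    def retained(self) -> int:
        return len(self.draws)

    def summary(self, ess: bool = False) -> pd.DataFrame:
        """Posterior mean, equal-tailed 95% interval, pMCMC (and ESS)."""
        rows = []
        for name in self.draws.columns:
            d = self.draws[name].to_numpy()
            lo, hi = np.quantile(d, [0.025, 0.975])
            is_var = name in ("sigma_a2", "sigma_e2")
            rows.append({
                "coefficient": name, "post_mean": float(d.mean()),
                "l95": float(lo), "u95": float(hi),
                "pmcmc": np.nan if is_var else pmcmc(d),
                **({"ess": _ess(d)} if ess else {}),
            })
        return pd.DataFrame(rows).set_index("coefficient")


# ---------------------------------------------------------------------------
# design construction

_FULL_TERMS = ("year", "class_mammal", "habitat_terrestrial", "abs_latitude",
               "longitude", "sex_male", "series_length")
_PERIOD_TERMS = ("year", "abs_latitude", "longitude", "sex_male")


def build_design(records: RecordTable, meta: dict[str, SpeciesMeta] | None,
                 model: str = "A") -> tuple[pd.DataFrame, list]:
    """Fixed-effect design matrix for one of the model variants.

    Models A/B/C carry the full term set (class and habitat fixed factors
    plus covariates); B adds year x class, C adds year x habitat. Model
    "period" uses only year, |latitude|, longitude and sex, as in the
    per-period analyses. Reference levels folded into the intercept:
    class = bird, habitat = aquatic, sex = female. Constant columns are
    dropped with a warning.
    """
    df = records.df
    cols = {"intercept": np.ones(len(df))}
    if model in ("A", "B", "C"):
        if meta is None:
            raise ValueError("models A/B/C need species metadata")
        cls = df["species_id"].map(lambda s: meta[s].taxo_class)
        hab = df["species_id"].map(lambda s: meta[s].habitat)
        cols["year"] = df["year"].to_numpy(float)
        cols["class_mammal"] = (cls == "mammal").to_numpy(float)
        cols["habitat_terrestrial"] = (hab == "terrestrial").to_numpy(float)
        cols["abs_latitude"] = df["latitude"].abs().to_numpy(float)
        cols["longitude"] = df["longitude"].to_numpy(float)
        cols["sex_male"] = (df["sex"] == "male").to_numpy(float)
        cols["series_length"] = df["species_id"].map(
            lambda s: meta[s].series_length).to_numpy(float)
        if model == "B":
            cols["year_x_class_mammal"] = cols["year"] * cols["class_mammal"]
        elif model == "C":
            cols["year_x_habitat_terrestrial"] = (
                cols["year"] * cols["habitat_terrestrial"])
    elif model == "period":
        cols["year"] = df["year"].to_numpy(float)
        cols["abs_latitude"] = df["latitude"].abs().to_numpy(float)
        cols["longitude"] = df["longitude"].to_numpy(float)
        cols["sex_male"] = (df["sex"] == "male").to_numpy(float)
    else:
        raise ValueError(f"unknown model {model!r}")

    X = pd.DataFrame(cols)
    dropped = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant design columns: {dropped}",
                      stacklevel=2)
        X = X.drop(columns=dropped)
    return X, dropped


# ---------------------------------------------------------------------------
# Gibbs sampler

def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def _chol_with_jitter(M: np.ndarray, jitter: float = 1e-8,
                      what: str = "matrix") -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.cholesky(M + jitter * np.eye(len(M)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"{what} is not positive definite even after jitter") from exc


def _gibbs(y, X, Z, A, priors: PriorSpec, config: ChainConfig):
    """Blocked conjugate Gibbs sampler for the Gaussian mixed model.

    Joint draw of (fixed effects, species effects) from the mixed-model
    Gaussian full conditional, then the variance components from
    inverse-gamma full conditionals. Cross-products are precomputed once;
    each iteration costs one Cholesky of a (p+q) x (p+q) matrix.
    """
    y = np.asarray(y, float)
    n, p = X.shape
    q = Z.shape[1]
    W = np.hstack([np.asarray(X, float), np.asarray(Z, float)])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    La = _chol_with_jitter(A, what="phylogenetic covariance")
    Ainv = linalg.cho_solve((La, True), np.eye(q))
    Ainv = (Ainv + Ainv.T) / 2

    V = priors.scale if priors.scale is not None else float(np.var(y) / 2)
    if V <= 0:
        raise ValueError("response variance is zero; cannot set prior scale")
    nu = priors.nu
    prior_prec_fix = 1.0 / priors.v_fix

    rng = np.random.default_rng(config.seed)
    sa2 = priors.fixed_phylo_variance if priors.fixed_phylo_variance is not None else V
    se2 = float(np.var(y))
    fixed_sa2 = priors.fixed_phylo_variance is not None

    retained = config.retained
    theta_draws = np.empty((retained, p + q))
    var_draws = np.empty((retained, 2))
    dev_draws = np.empty(retained)
    log2pi = np.log(2 * np.pi)
    k = 0
    diag_p = np.arange(p)
    for it in range(config.total):
        C = WtW / se2
        C[diag_p, diag_p] += prior_prec_fix
        C[p:, p:] += Ainv / sa2
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"full-conditional precision not PD at iteration {it}") from exc
        mean = linalg.cho_solve((L, True), Wty / se2, check_finite=False)
        zdraw = rng.standard_normal(p + q)
        theta = mean + linalg.solve_triangular(L, zdraw, trans="T",
                                               lower=True, check_finite=False)
        u = theta[p:]
        if not fixed_sa2:
            quad = float(u @ Ainv @ u)
            sa2 = _inv_gamma(rng, (nu + q) / 2, (nu * V + quad) / 2)
        ee = yty - 2 * theta @ Wty + theta @ (WtW @ theta)
        ee = max(float(ee), 1e-300)
        se2 = _inv_gamma(rng, (nu + n) / 2, (nu * V + ee) / 2)
        if not (np.isfinite(se2) and np.isfinite(sa2)):
            raise ValueError(f"divergent variance draw at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            theta_draws[k] = theta
            var_draws[k] = (sa2, se2)
            dev_draws[k] = n * (log2pi + np.log(se2)) + ee / se2
            k += 1
    assert k == retained

    # DIC conditional on the species effects (random effects in focus)
    theta_bar = theta_draws.mean(axis=0)
    se2_bar = var_draws[:, 1].mean()
    ee_hat = yty - 2 * theta_bar @ Wty + theta_bar @ (WtW @ theta_bar)
    d_hat = n * (log2pi + np.log(se2_bar)) + ee_hat / se2_bar
    d_bar = float(dev_draws.mean())
    p_d = d_bar - d_hat
    dic = d_bar + p_d
    return theta_draws, var_draws, dev_draws, dic, p_d


class PhylogeneticGLMM(BaseEstimator):
    """Phylogenetic mixed model of standardized body mass, fit by Gibbs sampling.

    Parameters
    ----------
    model : {"A", "B", "C", "period"}
        Fixed-effect structure: A = class + habitat + covariates,
        B = A + year x class, C = A + year x habitat, "period" = year +
        |latitude| + longitude + sex only.
    standardize : {"within_species", "global", "none"}
        Response standardization scope.
    scaling : {"unit_diagonal", "raw"}
        Scaling of the phylogenetic covariance matrix.
    center_year : bool
        Center year (and its interactions) at the mean collection year for
        numerical conditioning; coefficients are reported back on the raw
        calendar-year scale either way.
    priors : PriorSpec
    total, burn_in, thin : int
        Chain lengths (see :class:`ChainConfig`).
    random_state : int
        Seed for the sampler.

    Attributes
    ----------
    chain_ : PosteriorChain
    summary_ : DataFrame of posterior means, 95% CIs and pMCMC
    dic_ : float
    coef_names_, species_, dropped_columns_
    """

    def __init__(self, model: str = "A", standardize: str = "within_species",
                 scaling: str = "unit_diagonal", center_year: bool = False,
                 priors: PriorSpec | None = None, total: int = 250_000,
                 burn_in: int = 50_000, thin: int = 100,
                 random_state: int = 0):
        self.model = model
        self.standardize = standardize
        self.scaling = scaling
        self.center_year = center_year
        self.priors = priors
        self.total = total
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state

    def fit(self, records: RecordTable, meta: dict[str, SpeciesMeta] | None = None,
            tree: dendropy.Tree | None = None):
        if tree is None:
            raise ValueError("a phylogeny is required (tree=...)")
        species = records.species
        cov = phylo_covariance(tree, scaling=self.scaling,
                               species_order=species)
        X, dropped = build_design(records, meta, model=self.model)
        names = list(X.columns)
        Xm = X.to_numpy(float)

        year_cols = [i for i, c in enumerate(names)
                     if c == "year" or c.startswith("year_x_")]
        shift = 0.0
        if self.center_year and "year" in names:
            shift = float(records.df["year"].mean())
            for i in year_cols:
                c = names[i]
                if c == "year":
                    Xm[:, i] = Xm[:, i] - shift
                else:  # year * indicator -> (year - shift) * indicator
                    ind = c.replace("year_x_", "")
                    Xm[:, i] = Xm[:, i] - shift * X[ind].to_numpy(float)

        sp_index = {s: j for j, s in enumerate(species)}
        Z = np.zeros((len(records.df), len(species)))
        Z[np.arange(len(records.df)),
          records.df["species_id"].map(sp_index).to_numpy()] = 1.0

        y = standardize_mass(records, scope=self.standardize).to_numpy()
        priors = self.priors if self.priors is not None else PriorSpec()
        config = ChainConfig(total=self.total, burn_in=self.burn_in,
                             thin=self.thin, seed=self.random_state)
        theta, var_draws, dev, dic, p_d = _gibbs(
            y, Xm, Z, cov.matrix, priors, config)

        p = len(names)
        fixed = theta[:, :p].copy()
        if shift:
            # undo centering: beta0_raw = beta0 - shift * beta_year (per
            # year-carrying column, onto the matching main-effect column)
            i_int = names.index("intercept")
            for i in year_cols:
                c = names[i]
                if c == "year":
                    fixed[:, i_int] -= shift * fixed[:, i]
                else:
                    j = names.index(c.replace("year_x_", ""))
                    fixed[:, j] -= shift * fixed[:, i]

        draws = pd.DataFrame(fixed, columns=names)
        draws["sigma_a2"] = var_draws[:, 0]
        draws["sigma_e2"] = var_draws[:, 1]
        self.chain_ = PosteriorChain(
            coef_names=names, draws=draws, deviance=dev, dic=dic, p_d=p_d,
            config=config, species=species,
            species_effects=pd.DataFrame(theta[:, p:], columns=species))
        self.summary_ = self.chain_.summary()
        self.dic_ = dic
        self.coef_names_ = names
        self.species_ = species
        self.dropped_columns_ = dropped
        self._meta = meta
        self._cov = cov
        return self

    def predict(self, records: RecordTable) -> np.ndarray:
        """Posterior-mean prediction of the standardized response."""
        X, _ = build_design(records, self._meta, model=self.model)
        beta = self.summary_.loc[self.coef_names_, "post_mean"].to_numpy()
        Xm = X[self.coef_names_].to_numpy(float)
        u = self.chain_.species_effects.mean(axis=0)
        uvec = records.df["species_id"].map(u).fillna(0.0).to_numpy()
        return Xm @ beta + uvec


# ---------------------------------------------------------------------------
# posterior contrasts between two chains

@dataclass
class ContrastResult:
    """Iteration-wise coefficient differences between two chains (b - a)."""

    diffs: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.diffs.columns:
            d = self.diffs[name].to_numpy()
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({"coefficient": name, "post_mean": float(d.mean()),
                         "l95": float(lo), "u95": float(hi),
                         "pmcmc": pmcmc(d)})
        return pd.DataFrame(rows).set_index("coefficient")


def coefficient_contrast(chain_a: PosteriorChain, chain_b: PosteriorChain,
                         coefficients=None) -> ContrastResult:
    """Posterior distribution of chain_b minus chain_a, paired by iteration.

    Both chains must have the same retained-sample count (re-run with a
    matching ChainConfig otherwise). The difference distribution is
    summarized exactly like a coefficient: mean, equal-tailed 95%
    interval, pMCMC.
    """
    if chain_a.retained != chain_b.retained:
        raise ValueError(
            f"retained-sample counts differ ({chain_a.retained} vs "
            f"{chain_b.retained}); re-run with a matching ChainConfig")
    if coefficients is None:
        coefficients = [c for c in chain_a.coef_names
                        if c in chain_b.coef_names]
    missing = [c for c in coefficients
               if c not in chain_a.draws.columns or c not in chain_b.draws.columns]
    if missing:
        raise ValueError(f"coefficients absent from a chain: {missing}")
    diffs = pd.DataFrame({
        c: chain_b.draws[c].to_numpy() - chain_a.draws[c].to_numpy()
        for c in coefficients})
    return ContrastResult(diffs=diffs)
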