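"""Synthetic genotype-phenotype simulation framework.

Generates every input the association-testing experiments need:

* genotypes: i.i.d. binomial SNPs, or mosaic cohorts built from synthetic
  Balding-Nichols founder populations (population stratification and
  relatedness controlled by the number of ancestors per individual);
* trait covariance structures (equicorrelation or random Wishart-type);
* residual families: multivariate normal, multivariate t (3 df), Gaussian
  copulas with uniform / beta(0.5, 0.5) / gamma(1, 10) marginals, points in
  the simplex, multinomial counts;
* phenotypes under the additive model Y = x b' + U + E with exact
  (realized) variance-fraction rescaling for the variant and the
  population-structure terms;
* the balanced two-factor crossed design used to compare asymptotic and
  permutation tests;
* plain-text writers (VCF, TSV) so the GWAS front end is testable
  end-to-end without external data.

Variance fractions (h2_v, h2_g) are *global*: the fraction of the total
phenotypic variance, summed over the q traits, carried by the variant and
the population-structure terms.  Rescaling is exact on the realized sample
variances, not in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "SimScenario",
    "SimplexGenerator",
    "sim_binomial_snps",
    "make_founders",
    "sim_mosaic_cohort",
    "relatedness",
    "make_sigma",
    "sim_residuals",
    "simplex_point",
    "geodesic_shift",
    "simplex_sample",
    "sim_phenotypes",
    "sim_simplex_phenotypes",
    "sim_two_factor",
    "write_vcf",
    "write_traits_tsv",
]


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeMatrix:
    """Allele-dose matrix: n individuals x m variants, entries in {0,1,2}.

    ``-1`` encodes a missing call (only introduced by :func:`add_missing`).
    """

    values: np.ndarray
    maf: np.ndarray  # declared per-variant MAF (generator parameter)
    pop_labels: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not self.sample_ids:
            self.sample_ids = [f"S{i:04d}" for i in range(self.values.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def sim_binomial_snps(n: int, m: int, maf, rng) -> GenotypeMatrix:
    """i.i.d. biallelic SNP doses x ~ Binomial(2, MAF).

    ``maf`` may be a scalar, an array of length m, or a (lo, hi) tuple from
    which per-variant MAFs are drawn uniformly.
    """
    rng = np.random.default_rng(rng)
    if isinstance(maf, tuple):
        maf = rng.uniform(maf[0], maf[1], size=m)
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (m,)).copy()
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("MAF must lie in (0, 0.5]")
    doses = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    return GenotypeMatrix(values=doses, maf=maf)


def make_founders(
    n_pops: int,
    founders_per_pop: int,
    m: int,
    fst: float = 0.01,
    rng=None,
) -> GenotypeMatrix:
    """Synthetic founder populations (Balding-Nichols allele frequencies).

    Ancestral frequencies are drawn U(0.05, 0.95); each subpopulation's
    frequency is Beta-distributed around the ancestral one with divergence
    F_ST.  A synthetic stand-in for real reference-panel haplotypes.
    """
    rng = np.random.default_rng(rng)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    shape = (1.0 - fst) / fst
    doses = np.empty((n_pops * founders_per_pop, m), dtype=np.int8)
    labels = np.empty(n_pops * founders_per_pop, dtype=object)
    for k in range(n_pops):
        p_k = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        rows = slice(k * founders_per_pop, (k + 1) * founders_per_pop)
        doses[rows] = rng.binomial(2, p_k, size=(founders_per_pop, m))
        labels[rows] = f"POP{k + 1}"
    return GenotypeMatrix(values=doses, maf=p_anc, pop_labels=labels)


def sim_mosaic_cohort(
    founders: GenotypeMatrix,
    n: int,
    A: int,
    block_size: int = 1000,
    stratified: bool = False,
    rng=None,
) -> GenotypeMatrix:
    """Mosaic individuals: blocks of ``block_size`` variants, each copied
    from one of ``A`` ancestors chosen at random per individual.

    Small ``A`` (e.g. 2) yields strong relatedness; large ``A`` (e.g. 10)
    approximately unrelated individuals.  With ``stratified=True`` each
    individual's ancestors come from a single founder population, inducing
    population stratification.
    """
    rng = np.random.default_rng(rng)
    if A < 1:
        raise ValueError("need A >= 1 ancestors")
    m = founders.m
    n_blocks = int(np.ceil(m / block_size))
    doses = np.empty((n, m), dtype=np.int8)
    labels = np.empty(n, dtype=object)
    pops = (
        np.unique(founders.pop_labels) if founders.pop_labels is not None else None
    )
    for i in range(n):
        if stratified:
            if pops is None:
                raise ValueError("stratified cohorts need founder pop labels")
            pop = pops[rng.integers(len(pops))]
            pool = np.flatnonzero(founders.pop_labels == pop)
            labels[i] = pop
        else:
            pool = np.arange(founders.n)
            labels[i] = "ALL"
        if pool.size < A:
            raise ValueError(
                f"only {pool.size} founders available for {A} ancestors"
            )
        ancestors = rng.choice(pool, size=A, replace=False)
        picks = ancestors[rng.integers(A, size=n_blocks)]
        per_variant = np.repeat(picks, block_size)[:m]
        doses[i] = founders.values[per_variant, np.arange(m)]
    return GenotypeMatrix(values=doses, maf=founders.maf, pop_labels=labels)


def relatedness(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Genetic relatedness matrix K = (1/g) G_cs G_cs' on the centered and
    unit-variance-scaled dose matrix; monomorphic variants are dropped."""
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    X = X.astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Z @ Z.T / Z.shape[1]


def add_missing(G: GenotypeMatrix, rate: float, rng=None) -> GenotypeMatrix:
    """Set a random fraction of calls to missing (-1)."""
    rng = np.random.default_rng(rng)
    vals = G.values.copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = -1
    return GenotypeMatrix(
        values=vals, maf=G.maf, pop_labels=G.pop_labels, sample_ids=G.sample_ids
    )


# ---------------------------------------------------------------------------
# covariance structures and residual families


def make_sigma(
    q: int,
    r: float | None = None,
    variances=None,
    random: bool = False,
    rng=None,
) -> np.ndarray:
    """Trait covariance: equicorrelation V^1/2 R V^1/2, or random AA'.

    ``variances`` may be None (unit), a scalar upper bound sigma2_max
    (variances equally spaced in [1, sigma2_max]) or a length-q vector.
    Random matrices (A with standard-normal entries) are redrawn until
    positive definite.
    """
    rng = np.random.default_rng(rng)
    if random:
        for _ in range(100):
            A = rng.standard_normal((q, q))
            sigma = A @ A.T
            if np.linalg.eigvalsh(sigma).min() > 1e-10 * np.abs(sigma).max():
                return sigma
        raise RuntimeError("failed to draw a positive-definite AA' matrix")
    r = 0.0 if r is None else float(r)
    R = np.full((q, q), r)
    np.fill_diagonal(R, 1.0)
    if variances is None:
        v = np.ones(q)
    elif np.ndim(variances) == 0:
        v = np.linspace(1.0, float(variances), q)
    else:
        v = np.asarray(variances, dtype=float)
    s = np.sqrt(v)
    sigma = s[:, None] * R * s[None, :]
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise ValueError(f"equicorrelation r={r} is not positive definite for q={q}")
    return sigma


def _cov_to_corr_scaled(sigma: np.ndarray, c: float) -> np.ndarray:
    """Scale off-diagonal correlations by c while keeping variances fixed."""
    out = sigma * c
    np.fill_diagonal(out, np.diag(sigma))
    return out


def _copula_draw(n: int, q: int, R: np.ndarray, marginal: str, rng) -> np.ndarray:
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, q)) @ L.T
    U = stats.norm.cdf(Z)
    if marginal == "uniform":
        Y = U
    elif marginal == "beta":
        Y = stats.beta.ppf(U, 0.5, 0.5)
    elif marginal == "gamma":
        Y = stats.gamma.ppf(U, a=1.0, scale=10.0)
    else:
        raise ValueError(f"unknown copula marginal {marginal!r}")
    # residuals are centered and scaled per trait
    return (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)


def sim_residuals(
    family: str,
    n: int,
    q: int,
    sigma: np.ndarray | None = None,
    marginal: str = "uniform",
    simplex_p: np.ndarray | None = None,
    sigma_g: float = 0.05,
    n_trials: int = 1000,
    rng=None,
) -> np.ndarray:
    """n x q residual draws from one of the supported families.

    ``mvnorm``: N(0, sigma).  ``mvt3``: multivariate t, 3 df, scale sigma.
    ``copula``: Gaussian copula with the given marginal, centered/scaled.
    ``simplex``: points in the (q-1)-simplex around ``simplex_p``.
    ``multinomial``: counts M(n_trials, p).
    """
    rng = np.random.default_rng(rng)
    if sigma is None:
        sigma = np.eye(q)
    if family == "mvnorm":
        L = np.linalg.cholesky(sigma)
        return rng.standard_normal((n, q)) @ L.T
    if family == "mvt3":
        L = np.linalg.cholesky(sigma)
        Z = rng.standard_normal((n, q)) @ L.T
        w = rng.chisquare(3, size=n) / 3.0
        return Z / np.sqrt(w)[:, None]
    if family == "copula":
        R = _cov_to_corr(sigma)
        return _copula_draw(n, q, R, marginal, rng)
    if family == "simplex":
        p = simplex_p if simplex_p is not None else simplex_point(q, 1.0)
        return simplex_sample(SimplexGenerator(p=p, sigma_g=sigma_g), n, rng)
    if family == "multinomial":
        p = simplex_p if simplex_p is not None else simplex_point(q, 1.0)
        return rng.multinomial(n_trials, p, size=n).astype(float)
    raise ValueError(f"unknown residual family {family!r}")


def _cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    s = np.sqrt(np.diag(sigma))
    return sigma / np.outer(s, s)


# ---------------------------------------------------------------------------
# simplex generator


def simplex_point(q: int, L: float) -> np.ndarray:
    """Location p with p1 = L/(q+L-1) and pj = 1/(q+L-1) for j > 1.

    L = 1 is the simplex center; larger L moves p toward the vertex e1.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    p = np.full(q, 1.0 / (q + L - 1.0))
    p[0] = L / (q + L - 1.0)
    return p


def geodesic_shift(p: np.ndarray, delta: float, direction: int = 0) -> np.ndarray:
    """Shift p along the Hellinger-sphere geodesic toward vertex e_direction.

    The square roots of compositions live on the unit sphere; the shift
    moves sqrt(p) along the great circle joining it with the vertex by an
    arc fraction ``delta`` (negative delta moves away, mirroring +delta).
    Raises if the shifted point leaves the open simplex.
    """
    p = np.asarray(p, dtype=float)
    s = np.sqrt(p)
    e = np.zeros_like(s)
    e[direction] = 1.0
    cosphi = np.clip(np.dot(s, e), -1.0, 1.0)
    phi = np.arccos(cosphi)
    if phi == 0:
        raise ValueError("p already lies at the target vertex")
    t = delta * phi
    s_new = (np.sin(phi - t) * s + np.sin(t) * e) / np.sin(phi)
    p_new = s_new**2
    if np.any(s_new < 0) or not np.all(p_new > 0):
        raise ValueError(f"delta = {delta} pushes the point outside the simplex")
    return p_new / p_new.sum()


@dataclass
class SimplexGenerator:
    """Random compositions around p: vertex-directed displacements.

    A vertex e_j is chosen with probability p_j and the sample is
    y = p + delta * (e_j - p) with delta = min(|N(0, sigma_g)|, 1).  Since
    sum_j p_j e_j = p, E(y) = p exactly, and y stays in the simplex.
    """

    p: np.ndarray
    sigma_g: float = 0.05

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p <= 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must be an interior point of the simplex")


def simplex_sample(gen: SimplexGenerator, n: int, rng=None) -> np.ndarray:
    rng = np.random.default_rng(rng)
    q = gen.p.size
    j = rng.choice(q, size=n, p=gen.p)
    delta = np.minimum(np.abs(rng.normal(0.0, gen.sigma_g, size=n)), 1.0)
    E = np.eye(q)[j]
    return gen.p[None, :] + delta[:, None] * (E - gen.p[None, :])


# ---------------------------------------------------------------------------
# phenotype simulation


@dataclass
class SimScenario:
    """Full parameterization of one simulation cell.

    Defaults are the central study conditions: 1000 individuals, 3 traits,
    multivariate normal residuals with unit variances and no correlation,
    20% of variance from population structure when a kinship matrix is
    supplied, and a mid-range variant effect (h2_v = 0.005) on all traits.
    """

    n: int = 1000
    q: int = 3
    residual_family: str = "mvnorm"
    copula_marginal: str = "uniform"
    r: float | None = 0.0
    random_sigma: bool = False
    sigma2_max: float | None = None
    tau: float | None = None
    tau_mode: str = "covariance"  # or "correlation_only"
    h2_v: float = 0.005
    h2_g: float = 0.0
    beta_pattern: str = "equal"  # {"equal", "spaced", "proportions", "null"}
    beta_max: float = 2.0
    n_traits_affected: int | None = None
    sigma_g: float = 0.05
    simplex_L: float = 1.0
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0

    def sigma(self, rng=None) -> np.ndarray:
        return make_sigma(
            self.q,
            r=self.r,
            variances=self.sigma2_max,
            random=self.random_sigma,
            rng=rng,
        )

    def beta(self) -> np.ndarray:
        t = self.n_traits_affected or self.q
        if t > self.q:
            raise ValueError("n_traits_affected cannot exceed q")
        b = np.zeros(self.q)
        if self.beta_pattern == "null":
            return b
        if self.beta_pattern == "equal":
            b[:t] = 1.0
        elif self.beta_pattern == "spaced":
            b[:t] = np.linspace(1.0, self.beta_max, t)
        elif self.beta_pattern == "proportions":
            b[0] = 1.0
            b[1:] = -1.0 / (self.q - 1)
        else:
            raise ValueError(f"unknown beta pattern {self.beta_pattern!r}")
        return b


def kinship_sqrt(K: np.ndarray) -> np.ndarray:
    """Symmetric square root of a relatedness matrix (eigenvalues clipped)."""
    lamk, Vk = np.linalg.eigh(K)
    return Vk * np.sqrt(np.clip(lamk, 0.0, None))


def _matrix_normal(K_sqrt: np.ndarray, sigma_u: np.ndarray, rng) -> np.ndarray:
    """Draw U ~ MN(0, K, sigma_u) given a square root of K."""
    Lu = np.linalg.cholesky(sigma_u + 1e-12 * np.eye(sigma_u.shape[0]))
    Z = rng.standard_normal((K_sqrt.shape[1], sigma_u.shape[0]))
    return K_sqrt @ Z @ Lu.T


def _total_var(M: np.ndarray) -> float:
    return float(np.sum(np.var(M, axis=0, ddof=1)))


def _hetero_residuals(x: np.ndarray, scen: SimScenario, sigma, rng) -> np.ndarray:
    """Residuals with genotype-group heterogeneity.

    covariance mode: groups 0/1/2 get Sigma, (tau+1)/2*Sigma, tau*Sigma.
    correlation_only: correlations scaled to R, 2/(tau+1)*R, 1/tau*R with
    variances unchanged.
    """
    tau = scen.tau
    n, q = x.size, scen.q
    E = np.empty((n, q))
    if scen.tau_mode == "covariance":
        covs = [sigma, 0.5 * (tau + 1.0) * sigma, tau * sigma]
    elif scen.tau_mode == "correlation_only":
        covs = [
            sigma,
            _cov_to_corr_scaled(sigma, 2.0 / (tau + 1.0)),
            _cov_to_corr_scaled(sigma, 1.0 / tau),
        ]
    else:
        raise ValueError(f"unknown tau mode {scen.tau_mode!r}")
    chols = [np.linalg.cholesky(c) for c in covs]
    Z = rng.standard_normal((n, q))
    for g in (0, 1, 2):
        rows = x == g
        E[rows] = Z[rows] @ chols[g].T
    return E


def sim_phenotypes(
    scenario: SimScenario,
    x: np.ndarray | None = None,
    K: np.ndarray | None = None,
    K_sqrt: np.ndarray | None = None,
    rng=None,
    maf: float = 0.2,
):
    """Simulate Y = x b' + U + E under one scenario.

    ``x`` is the causal-variant dose vector (drawn Binomial(2, maf) if not
    given); ``K`` the relatedness matrix driving the matrix-normal
    population-structure term (required when h2_g > 0).  Components are
    rescaled so the realized global variance fractions of the variant and
    structure terms equal h2_v and h2_g exactly.  Returns ``(Y, truth)``
    where ``truth`` records every component and scale factor.
    """
    rng = np.random.default_rng(rng)
    scen = scenario
    if scen.h2_v + scen.h2_g >= 1:
        raise ValueError("h2_v + h2_g must be < 1")
    if x is None:
        x = rng.binomial(2, maf, size=scen.n)
    x = np.asarray(x, dtype=float)
    n, q = x.size, scen.q
    sigma = scen.sigma(rng)
    if scen.tau is not None:
        if scen.residual_family != "mvnorm":
            raise ValueError("genotype-group heterogeneity requires mvnorm residuals")
        E = _hetero_residuals(x.astype(int), scen, sigma, rng)
    else:
        E = sim_residuals(
            scen.residual_family,
            n,
            q,
            sigma=sigma,
            marginal=scen.copula_marginal,
            simplex_p=simplex_point(q, scen.simplex_L),
            sigma_g=scen.sigma_g,
            rng=rng,
        )
    if scen.outlier_rate > 0:
        rows = rng.random(n) < scen.outlier_rate
        E[rows] *= scen.outlier_scale
    beta = scen.beta()
    h2_v = scen.h2_v if scen.beta_pattern != "null" else 0.0
    Gc = np.outer(x, beta)
    if scen.h2_g > 0:
        if K_sqrt is None:
            if K is None:
                raise ValueError("h2_g > 0 requires a relatedness matrix K")
            K_sqrt = kinship_sqrt(K)
        sigma_u = make_sigma(q, random=True, rng=rng)
        U = _matrix_normal(K_sqrt, sigma_u, rng)
    else:
        U = np.zeros((n, q))
    # exact rescaling of realized (sample) variance fractions, summed over
    # traits: E keeps its natural scale and defines the residual share
    v_e = _total_var(E)
    h2_e = 1.0 - h2_v - scen.h2_g
    v_tot = v_e / h2_e
    s_g = np.sqrt(h2_v * v_tot / _total_var(Gc)) if h2_v > 0 else 0.0
    s_u = np.sqrt(scen.h2_g * v_tot / _total_var(U)) if scen.h2_g > 0 else 0.0
    Gc = Gc * s_g
    U = U * s_u
    Y = Gc + U + E
    truth = {
        "x": x,
        "beta": beta * s_g,
        "genetic": Gc,
        "structure": U,
        "residual": E,
        "scale_genetic": s_g,
        "scale_structure": s_u,
        "h2_v_realized": _total_var(Gc) / v_tot,
        "h2_g_realized": _total_var(U) / v_tot,
    }
    return Y, truth


def sim_simplex_phenotypes(
    x: np.ndarray,
    q: int,
    L: float = 1.0,
    sigma_g: float = 0.05,
    delta: float = 0.0,
    rng=None,
) -> np.ndarray:
    """Compositional traits with a genotype-dependent simplex location.

    Genotype groups 0/1/2 sample around p shifted by -delta / 0 / +delta
    along the geodesic toward e1, so the effect is additive on the sphere
    and the overall mean stays near p.
    """
    rng = np.random.default_rng(rng)
    p = simplex_point(q, L)
    locs = {1: p}
    locs[0] = geodesic_shift(p, -delta) if delta else p
    locs[2] = geodesic_shift(p, delta) if delta else p
    x = np.asarray(x, dtype=int)
    Y = np.empty((x.size, q))
    for g in (0, 1, 2):
        rows = np.flatnonzero(x == g)
        if rows.size:
            Y[rows] = simplex_sample(
                SimplexGenerator(p=locs[g], sigma_g=sigma_g), rows.size, rng
            )
    return Y


def sim_two_factor(
    n: int,
    q: int,
    family: str = "mvnorm",
    delta: float = 0.0,
    delta_interaction: float = 0.0,
    sigma_g: float = 0.05,
    L: float = 1.0,
    rng=None,
):
    """Balanced crossed two-factor design: A (2 levels) x B (3 levels).

    Under the alternative for B (``delta > 0``) the first and second B
    levels are mean-shifted by +delta and -delta on every trait (mvnorm /
    copula families) or displaced by +/-delta along the simplex geodesic
    (simplex / multinomial), keeping the overall mean at its null value.
    ``delta_interaction`` adds a zero-sum cell pattern to the A:B cells.
    Returns ``(Y, design)`` with design columns "A" and "B".
    """
    rng = np.random.default_rng(rng)
    cells = 6
    if n % cells:
        raise ValueError(f"n = {n} is not divisible by the {cells} design cells")
    per = n // cells
    A = np.repeat(["a1", "a2"], 3 * per)
    B = np.tile(np.repeat(["b1", "b2", "b3"], per), 2)
    design = pd.DataFrame({"A": A, "B": B})
    b_shift = {"b1": delta, "b2": -delta, "b3": 0.0}
    inter = {
        ("a1", "b1"): 1.0, ("a1", "b2"): -1.0, ("a1", "b3"): 0.0,
        ("a2", "b1"): -1.0, ("a2", "b2"): 1.0, ("a2", "b3"): 0.0,
    }
    if family in {"mvnorm", "mvt3", "copula"}:
        Y = sim_residuals(family, n, q, sigma=np.eye(q), rng=rng)
        shift = np.array([b_shift[b] for b in B])
        shift = shift + delta_interaction * np.array(
            [inter[(a, b)] for a, b in zip(A, B)]
        )
        Y = Y + shift[:, None]
    elif family in {"simplex", "multinomial"}:
        p = simplex_point(q, L)
        locs = {
            "b1": geodesic_shift(p, delta) if delta else p,
            "b2": geodesic_shift(p, -delta) if delta else p,
            "b3": p,
        }
        Y = np.empty((n, q))
        for lev, ploc in locs.items():
            rows = np.flatnonzero(B == lev)
            if family == "simplex":
                Y[rows] = simplex_sample(
                    SimplexGenerator(p=ploc, sigma_g=sigma_g), rows.size, rng
                )
            else:
                Y[rows] = rng.multinomial(1000, ploc, size=rows.size)
    else:
        raise ValueError(f"unsupported family {family!r} for two-factor design")
    return Y, design


# ---------------------------------------------------------------------------
# plain-text writers


def write_vcf(G: GenotypeMatrix, path, chrom: str = "1", start: int = 10_000,
              spacing: int = 100) -> None:
    """Write doses as a minimal diploid VCF (GT field only, 1-based pos)."""
    ref_alt = [("A", "G"), ("C", "T")]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j in range(G.m):
            ref, alt = ref_alt[j % 2]
            gts = "\t".join(gt_map[int(v)] for v in G.values[:, j])
            fh.write(
                f"{chrom}\t{start + j * spacing}\tv{j + 1}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_traits_tsv(values: np.ndarray, sample_ids, path, prefix: str = "trait") -> None:
    """Phenotype/covariate table: first column 'id', then named columns."""
    values = np.asarray(values)
    cols = [f"{prefix}{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)
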