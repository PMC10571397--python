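"""Experiment harness: type I error, power and inflation of the test.

Each experiment loops phenotype simulation (:mod:`mantapy.synthetic`) and
the asymptotic test over m replicate phenotype-genotype pairs, then
summarizes rejection rates.  The inflation factor ``lambda_X`` is the
p-value analogue of the genomic-control lambda:

    lambda_X = median(-log10 p_observed) / median(-log10 p_null)

with the null median equal to -log10(0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MantaModel
from .synthetic import (
    GenotypeMatrix,
    SimScenario,
    relatedness,
    sim_binomial_snps,
    sim_phenotypes,
)

__all__ = [
    "ExperimentResult",
    "type_I_error",
    "power",
    "lambda_X",
    "run_experiment",
    "genotype_pcs",
]


def type_I_error(p_values, alpha: float = 0.05):
    """Rejection rate under the null, with its binomial standard error."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    rate = float(np.mean(p <= alpha))
    se = float(np.sqrt(rate * (1.0 - rate) / m)) if m else np.nan
    return rate, se


def power(p_values, alpha: float = 0.05, m_tests: int = 1, adjust: str = "bonferroni"):
    """Rejection rate under the alternative at a multiplicity-adjusted level.

    With ``adjust="bonferroni"`` the per-test threshold is alpha / m_tests.
    """
    if adjust not in {"none", "bonferroni"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    thr = alpha / m_tests if adjust == "bonferroni" else alpha
    p = np.asarray(p_values, dtype=float)
    rate = float(np.mean(p <= thr))
    se = float(np.sqrt(rate * (1.0 - rate) / p.size)) if p.size else np.nan
    return rate, se


def adjust_pvalues(p_values, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown adjustment {method!r}")


def lambda_X(p_observed) -> float:
    """p-value based inflation factor (1 for a uniform p distribution)."""
    p = np.asarray(p_observed, dtype=float)
    return float(np.median(-np.log10(p)) / -np.log10(0.5))


@dataclass
class ExperimentResult:
    scenario: SimScenario
    m: int
    p_values: np.ndarray
    alpha: float
    rate: float  # type I error (null scenarios) or power (alternatives)
    rate_se: float
    adjusted: str
    lambda_x: float


def genotype_pcs(G: GenotypeMatrix | np.ndarray, k: int) -> np.ndarray:
    """Top-k principal component scores of the centered/scaled dose matrix.

    Sign convention: the largest-magnitude loading of each component is
    made positive, so scores are deterministic across runs.
    """
    if k == 0:
        X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
        return np.empty((X.shape[0], 0))
    from sklearn.decomposition import PCA

    X = (G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)).astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=k, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(Z)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def run_experiment(
    scenario: SimScenario,
    m: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    cohort: GenotypeMatrix | None = None,
    n_pcs: int = 0,
    maf: float = 0.2,
    m_tests: int = 1,
    adjust: str | None = None,
) -> ExperimentResult:
    """m replicate phenotype-genotype pairs -> rejection rate of the test.

    A fixed ``cohort`` (mosaic or real-structure stand-in) supplies the
    relatedness matrix for the population-structure term and, when
    ``n_pcs > 0``, genotype PCs entering the model as covariates.  Without
    a cohort, causal variants are fresh binomial SNPs each replicate.
    The tested term is always the genotype, placed last (Type I).
    """
    rng = np.random.default_rng(seed)
    K_sqrt = None
    pcs = None
    test_pool = None
    if cohort is not None:
        from .synthetic import GenotypeMatrix, kinship_sqrt

        # leave-out split: kinship/PCs from even variants, tested variants
        # from odd ones, so the structure term never contains the tested
        # variant's own outer product (an n/g artifact at small g)
        background = GenotypeMatrix(cohort.values[:, ::2], cohort.maf[::2])
        test_pool = cohort.values[:, 1::2]
        K_sqrt = kinship_sqrt(relatedness(background))
        if n_pcs > 0:
            pcs = genotype_pcs(background, n_pcs)
    elif scenario.h2_g > 0:
        raise ValueError("population-structure scenarios need a cohort")

    pc_cols = [f"PC{j + 1}" for j in range(n_pcs)] if pcs is not None else []
    formula = " + ".join(pc_cols + ["genotype"])
    pvals = np.empty(m)
    for i in range(m):
        if test_pool is not None:
            x = test_pool[:, rng.integers(test_pool.shape[1])].astype(float)
            if x.std() == 0:  # monomorphic in this cohort: redraw
                x = sim_binomial_snps(scenario.n, 1, maf, rng).values[:, 0].astype(float)
        else:
            x = rng.binomial(2, maf, size=scenario.n).astype(float)
        Y, _ = sim_phenotypes(scenario, x=x, K_sqrt=K_sqrt, rng=rng)
        data = pd.DataFrame({"genotype": x})
        if pcs is not None:
            for c, col in enumerate(pc_cols):
                data[col] = pcs[:, c]
        res = MantaModel(Y, data, formula, subset=["genotype"], ss_type="I").fit()
        pvals[i] = res.pvalue("genotype")

    is_null = scenario.beta_pattern == "null" or scenario.h2_v == 0
    if adjust is None:
        adjust = "none" if is_null else "bonferroni"
    rate, se = power(pvals, alpha=alpha, m_tests=m_tests, adjust=adjust)
    return ExperimentResult(
        scenario=scenario,
        m=m,
        p_values=pvals,
        alpha=alpha,
        rate=rate,
        rate_se=se,
        adjusted=adjust,
        lambda_x=lambda_X(pvals),
    )
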