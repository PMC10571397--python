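"""Permutational PERMANOVA: empirical null by row shuffling of Y.

Provides the classical permutation test (free or within-stratum restricted
schemes) and the distance-matrix (Gower) formulation of the pseudo-F, used
as an equivalence oracle for the trace form: with Euclidean distances the
two coincide.

Restricted permutation matters in factorial designs: with factors A and B
and B under the alternative, an exact test for A (or for A:B) controlling
for B requires shuffling rows only within the levels of B.  There is no
exact scheme for an interaction controlling for *both* main effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec, Term, TermPartition, build_designs, orth_basis
from .mmr import trace_statistic

__all__ = ["PermutationScheme", "permanova_perm", "gower_pseudoF", "permuted_stats"]


@dataclass
class PermutationScheme:
    """How to shuffle: ``free`` or ``within_levels`` of a stratum factor."""

    kind: str = "free"  # {"free", "within_levels"}
    stratum_variable: str | None = None
    n_perm: int = 999
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in {"free", "within_levels"}:
            raise ValueError(f"unknown permutation scheme {self.kind!r}")
        if self.kind == "within_levels" and not self.stratum_variable:
            raise ValueError("within_levels scheme requires a stratum variable")
        if self.n_perm < 99:
            raise ValueError("use at least 99 permutations")

    def draw_indices(self, data: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        """(n_perm, n) row-index matrix; rows shuffled per the scheme."""
        n = len(data)
        idx = np.tile(np.arange(n), (self.n_perm, 1))
        if self.kind == "free":
            for r in range(self.n_perm):
                rng.shuffle(idx[r])
            return idx
        strata = data[self.stratum_variable].astype(str).to_numpy()
        for lev in np.unique(strata):
            rows = np.flatnonzero(strata == lev)
            if rows.size < 2:
                raise ValueError(
                    f"stratum level {lev!r} has < 2 rows; cannot permute"
                )
            for r in range(self.n_perm):
                idx[r, rows] = rows[rng.permutation(rows.size)]
        return idx


def permuted_stats(
    Y: np.ndarray,
    partition: TermPartition,
    indices: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Pseudo-F recomputed for each permuted row order of Y (vectorized).

    The designs stay fixed; only Y rows move.  Per permutation,
    numerator = |Q'Y_pi|^2 - |Q0'Y_pi|^2 and denominator = |Y|^2 - |Q'Y_pi|^2
    (the total sum of squares is permutation-invariant).
    """
    Y = np.asarray(Y, dtype=float)
    Q = partition.Q_full
    Q0 = partition.Q_reduced
    tot = float(np.sum(Y * Y))
    df, rr = partition.df_term, partition.rank_resid
    out = np.empty(indices.shape[0])
    for s in range(0, indices.shape[0], chunk):
        block = indices[s : s + chunk]
        Yp = Y[block]  # (c, n, q)
        proj = np.tensordot(Yp, Q, axes=([1], [0]))  # (c, q, r)
        ss_full = np.einsum("cqr,cqr->c", proj, proj)
        proj0 = np.tensordot(Yp, Q0, axes=([1], [0]))
        ss_red = np.einsum("cqr,cqr->c", proj0, proj0)
        num = ss_full - ss_red
        den = tot - ss_full
        out[s : s + chunk] = (num / df) / (den / rr)
    return out


def permanova_perm(
    Y: np.ndarray,
    data: pd.DataFrame,
    spec: ModelSpec | str,
    term: str,
    scheme: PermutationScheme,
    ss_type: str = "I",
    categorical=None,
):
    """Permutation test for one term.

    Returns ``(p_perm, observed_F, permuted_Fs)`` with
    ``p_perm = (#{F_pi >= F_obs} + 1) / (P + 1)`` (ties counted as
    exceedances).  Raw rows of Y are shuffled; ``within_levels`` schemes
    shuffle only inside each stratum.  The smallest achievable p-value is
    1/(P+1).
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_formula(spec)
    term_obj = Term(tuple(v.strip() for v in term.split(":")))
    if term_obj not in spec.terms:
        raise ValueError(f"term {term!r} not in model")
    if (
        scheme.kind == "within_levels"
        and term_obj.variables == (scheme.stratum_variable,)
    ):
        raise ValueError(
            "stratum variable is the tested term itself: permuting within its "
            "levels leaves the statistic unchanged (no exact test exists)"
        )
    sub = ModelSpec(terms=spec.terms, tested_subset=[term_obj])
    part = build_designs(sub, data, ss_type=ss_type, categorical=categorical)[0]
    obs = trace_statistic(Y, part).pseudo_F
    rng = np.random.default_rng(scheme.seed)
    idx = scheme.draw_indices(data, rng)
    perm_F = permuted_stats(np.asarray(Y, float), part, idx)
    p = (np.count_nonzero(perm_F >= obs) + 1) / (scheme.n_perm + 1)
    return p, obs, perm_F


def gower_pseudoF(D: np.ndarray, partition: TermPartition):
    """Distance-based pseudo-F from Gower's centered inner-product matrix.

    G = -1/2 C D^2 C with C = I - 11'/n and D^2 the elementwise square;
    pseudo-F = [tr{(H-H0)G}/df] / [tr{(I-H)G}/rank(I-H)].  For Euclidean D
    this equals the trace-form statistic; non-Euclidean-embeddable D (G with
    negative eigenvalues) is computed anyway with a warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("D must be symmetric, non-negative, zero-diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eig_min = np.linalg.eigvalsh(G).min()
    if eig_min < -1e-8 * max(1.0, np.abs(G).max()):
        import warnings

        warnings.warn(
            "distance matrix is not Euclidean-embeddable (negative Gower "
            "eigenvalues); pseudo-F computed on the indefinite form",
            stacklevel=2,
        )
    Q = partition.Q_full if partition.Q_full is not None else orth_basis(partition.X_full)
    Q0 = (
        partition.Q_reduced
        if partition.Q_reduced is not None
        else orth_basis(partition.X_reduced)
    )
    tr_full = float(np.einsum("ni,nm,mi->", Q, G, Q))
    tr_red = float(np.einsum("ni,nm,mi->", Q0, G, Q0))
    num = tr_full - tr_red
    den = float(np.trace(G)) - tr_full
    if partition.rank_resid > 0 and den != 0:
        F = (num / partition.df_term) / (den / partition.rank_resid)
    else:
        F = np.nan  # saturated design: no residual distance left
    return GowerStatistic(numerator=num, denominator=den, pseudo_F=F)


@dataclass
class GowerStatistic:
    """Distance-form traces and pseudo-F; floats as the pseudo-F."""

    numerator: float
    denominator: float
    pseudo_F: float

    def __float__(self) -> float:
        return float(self.pseudo_F)
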