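"""Multivariate multiple regression fit and the trace pseudo-F statistic.

For the model Y = X beta + E the statistic for a tested term is

    F = [ tr{Y'(H - H0)Y} / rank(H - H0) ] / [ tr{Y'(I - H)Y} / rank(I - H) ]

with H, H0 the hat matrices of the full and reduced designs.  All traces are
computed from orthonormal bases of the design column spaces (never from
materialized n x n projectors), so the cost is O(n p q) per statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import TermPartition, orth_basis

__all__ = ["FitResult", "fit_mmr", "trace_statistic", "TraceStatistic"]

#: relative tolerance below which a (round-off) negative numerator is clipped
_NEG_TOL = 1e-8


@dataclass
class FitResult:
    """OLS fit of the full model of a :class:`TermPartition`."""

    beta_hat: np.ndarray  # p x q
    residuals: np.ndarray  # n x q
    sigma_hat: np.ndarray  # q x q residual covariance
    lambdas: np.ndarray  # eigenvalues of sigma_hat, descending, >= 0
    rank_resid: int  # n - rank(H)


def fit_mmr(Y: np.ndarray, partition: TermPartition) -> FitResult:
    """Fit the full model by OLS and eigendecompose the residual covariance.

    ``sigma_hat = Y'(I-H)Y / (n - rank(H))``; its eigenvalues (clipped at 0)
    are the weights of the asymptotic null of the trace statistic.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if partition.rank_resid < 1:
        raise ValueError(
            "no residual degrees of freedom: n <= rank of the full design"
        )
    X = partition.X_full
    beta_hat, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Q = partition.Q_full if partition.Q_full is not None else orth_basis(X)
    residuals = Y - Q @ (Q.T @ Y)
    sigma_hat = residuals.T @ residuals / partition.rank_resid
    lam = np.linalg.eigvalsh(sigma_hat)[::-1]
    lam = np.clip(lam, 0.0, None)
    return FitResult(
        beta_hat=beta_hat,
        residuals=residuals,
        sigma_hat=sigma_hat,
        lambdas=lam,
        rank_resid=partition.rank_resid,
    )


@dataclass
class TraceStatistic:
    numerator: float  # tr{Y'(H - H0)Y}
    denominator: float  # tr{Y'(I - H)Y}
    pseudo_F: float
    df_term: int
    rank_resid: int


def trace_statistic(Y: np.ndarray, partition: TermPartition) -> TraceStatistic:
    """Numerator/denominator traces and the pseudo-F for one tested term."""
    Y = np.asarray(Y, dtype=float)
    Q = partition.Q_full
    Q0 = partition.Q_reduced
    if Q is None or Q0 is None:
        Q = orth_basis(partition.X_full)
        Q0 = orth_basis(partition.X_reduced)
    tot = float(np.sum(Y * Y))
    ss_full = float(np.sum((Q.T @ Y) ** 2))
    ss_red = float(np.sum((Q0.T @ Y) ** 2))
    num = ss_full - ss_red
    den = tot - ss_full
    # traces at the round-off floor of the total SS are exact zeros
    floor = 1e-12 * max(tot, 1.0)
    if 0 < num < floor:
        num = 0.0
    if 0 < den < floor:
        den = 0.0
    if num < 0:
        if num < -_NEG_TOL * max(tot, 1.0):
            raise FloatingPointError(
                f"negative numerator trace beyond tolerance: {num}"
            )
        num = 0.0
    if den <= 0 and partition.rank_resid > 0:
        # all response variation lies in the model column space
        if abs(den) > _NEG_TOL * max(tot, 1.0):
            raise ValueError("degenerate response: non-positive residual trace")
        den = 0.0
    df = partition.df_term
    rr = partition.rank_resid
    if den > 0 and rr > 0:
        F = (num / df) / (den / rr)
    else:
        F = 0.0 if num == 0 else np.inf
    return TraceStatistic(
        numerator=num,
        denominator=den,
        pseudo_F=F,
        df_term=df,
        rank_resid=rr,
    )
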