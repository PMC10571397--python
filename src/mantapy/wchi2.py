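"""Survival function of a weighted sum of independent chi-square variables.

The asymptotic null of the trace statistic's numerator is

    T  ~  sum_j lambda_j * chisq_j(d),      lambda_j >= 0,

with a common number of degrees of freedom ``d`` for all components (the
rank difference between the full and reduced designs).  Two engines are
provided:

* :func:`sf_farebrother` -- Ruben's expansion of the CDF as an infinite
  series of central chi-square CDFs (Farebrother's algorithm).  Monotone in
  the statistic down to a precision floor of 1e-14; the default engine.
* :func:`sf_imhof` -- numerical inversion of the characteristic function
  (Imhof's integral).  Accurate to ~1e-10; below that the quadrature can
  return values <= 0, which are flagged, never silently clipped.

Weights contributing less than a fraction ``t = 1e-3`` of the total are
dropped before the series is evaluated (:func:`truncate_weights`): near-zero
weights slow the series down dramatically while moving the p-value by less
than the series tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate
from scipy.stats import chi2

__all__ = [
    "WeightedChiSqNull",
    "truncate_weights",
    "sf_farebrother",
    "sf_imhof",
    "asymptotic_pvalue",
    "SeriesDivergenceError",
    "PRECISION_FLOOR",
]

#: smallest p-value the Farebrother engine reports (flagged below this)
PRECISION_FLOOR = 1e-14

#: default relative-weight truncation threshold
WEIGHT_TRUNCATION = 1e-3


class SeriesDivergenceError(RuntimeError):
    """Ruben series failed to converge; carries the partial sum and bound."""

    def __init__(self, msg: str, partial: float, mass_deficit: float):
        super().__init__(msg)
        self.partial = partial
        self.mass_deficit = mass_deficit


@dataclass(frozen=True)
class WeightedChiSqNull:
    """Weights and common df of the limiting weighted chi-square mixture."""

    weights: np.ndarray
    df: int

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-d array")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        if not np.any(w > 0):
            raise ValueError("all weights are zero")
        if int(self.df) < 1:
            raise ValueError("df must be >= 1")


def rvs(null: WeightedChiSqNull, size: int, rng=None) -> np.ndarray:
    """Random draws of sum_j lambda_j chisq(df) (e.g. for null comparison)."""
    rng = np.random.default_rng(rng)
    draws = rng.chisquare(null.df, size=(size, null.weights.size))
    return draws @ null.weights


def truncate_weights(
    null: WeightedChiSqNull, t: float = WEIGHT_TRUNCATION
) -> WeightedChiSqNull:
    """Drop weights with lambda_j / sum(lambda) < t, preserving order."""
    if not 0 <= t < 1:
        raise ValueError("truncation threshold t must be in [0, 1)")
    w = null.weights
    keep = w / w.sum() >= t
    if not keep.any():  # defensive: keep the largest weight
        keep = w == w.max()
    return replace(null, weights=w[keep])


def _ruben_coefficients(lam: np.ndarray, d: int, k_max: int) -> tuple[np.ndarray, float]:
    """First k_max Ruben mixing coefficients and the mixing parameter beta."""
    lmin, lmax = lam.min(), lam.max()
    beta = 2.0 * lmin * lmax / (lmin + lmax)
    gamma = 1.0 - beta / lam  # in (-1, 1) since beta < 2*lmin
    c = np.empty(k_max)
    c[0] = np.exp(0.5 * d * np.sum(np.log(beta / lam)))
    if c[0] == 0.0:
        raise SeriesDivergenceError(
            "leading Ruben coefficient underflowed (extreme weight spread)",
            partial=np.nan,
            mass_deficit=1.0,
        )
    # h_k = (d/2) * sum_j gamma_j^k ; c_k = (1/k) sum_{r<k} h_{k-r} c_r
    h = np.empty(k_max)
    g = np.ones_like(gamma)
    for k in range(1, k_max):
        g *= gamma
        h[k] = 0.5 * d * g.sum()
    for k in range(1, k_max):
        c[k] = np.dot(h[1 : k + 1][::-1], c[:k]) / k
    return c, beta


def sf_farebrother(
    x: float,
    null: WeightedChiSqNull,
    max_terms: int = 100_000,
    tol: float = 1e-16,
) -> tuple[float, set[str]]:
    """P(sum_j lambda_j chisq(df) >= x) by the Ruben/Farebrother series.

    Returns ``(p, flags)``; ``flags`` contains ``"at_precision_limit"`` when
    the series value fell below 1e-14 (the reported p is then 1e-14).

    The survival function is a mixture sum_k c_k * SF_chisq(rho + 2k, x/beta)
    with sum_k c_k = 1; the series is summed in blocks until the unassigned
    mixture mass |1 - sum c_k| drops below ``tol``.
    """
    if x < 0:
        raise ValueError("statistic must be non-negative")
    lam = null.weights[null.weights > 0]
    d = int(null.df)
    if x == 0:
        return 1.0, set()
    rho = d * lam.size
    block = 64
    k_max = block
    c, beta = _ruben_coefficients(lam, d, k_max)
    total = 0.0
    cum_mass = 0.0
    k0 = 0
    y = x / beta
    while True:
        ks = np.arange(k0, k_max)
        terms = c[k0:k_max] * chi2.sf(y, rho + 2 * ks)
        total += terms.sum()
        cum_mass += c[k0:k_max].sum()
        # the mixture mass cannot resolve below accumulated round-off,
        # which grows with the series length
        eps = np.finfo(float).eps
        tol_eff = max(tol, 16 * eps, 8 * eps * np.sqrt(k_max))
        if abs(1.0 - cum_mass) < tol_eff and abs(terms[-1]) < tol_eff:
            break
        if k_max >= max_terms:
            raise SeriesDivergenceError(
                f"Ruben series did not converge within {max_terms} terms "
                f"(mass deficit {1.0 - cum_mass:.3e})",
                partial=total,
                mass_deficit=1.0 - cum_mass,
            )
        k0 = k_max
        k_max = min(2 * k_max, max_terms)
        c, beta = _ruben_coefficients(lam, d, k_max)
    flags: set[str] = set()
    p = float(total)
    if p < PRECISION_FLOOR:
        p = PRECISION_FLOOR
        flags.add("at_precision_limit")
    return min(p, 1.0), flags


def sf_imhof(
    x: float,
    null: WeightedChiSqNull,
    epsabs: float = 1e-13,
    epsrel: float = 1e-12,
    limit: int = 500,
) -> tuple[float, set[str]]:
    """P(sum_j lambda_j chisq(df) >= x) by Imhof's inversion integral.

    p = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u * rho(u)) du

    Unreliable below ~1e-10: non-positive results are returned as-is with an
    ``"imhof_nonpositive"`` flag so callers can fall back or report.
    """
    if x < 0:
        raise ValueError("statistic must be non-negative")
    if x == 0:
        return 1.0, set()
    lam = null.weights[null.weights > 0]
    d = float(null.df)
    w = 0.5 * x  # asymptotic oscillation frequency of the integrand

    def phi(u):  # bounded phase component
        return 0.5 * d * np.sum(np.arctan(lam * u))

    def rho(u):  # amplitude decay, ~ u^(q d / 2)
        return np.exp(0.25 * d * np.sum(np.log1p((lam * u) ** 2)))

    def integrand(u):
        return np.sin(phi(u) - w * u) / (u * rho(u))

    # sin(phi - w u) = sin(phi) cos(w u) - cos(phi) sin(w u): beyond a small
    # head interval, integrate the two Fourier components with QUADPACK's
    # oscillatory-weight routine, which handles the infinite tail exactly
    def f_cos(u):
        return np.sin(phi(u)) / (u * rho(u))

    def f_sin(u):
        return np.cos(phi(u)) / (u * rho(u))

    # the head must cover at least one oscillation period, else the Fourier
    # routine's cycle acceleration has nothing to accelerate
    a = min(max(1.0, 2.0 * np.pi / w), 1e5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        head, _ = integrate.quad(
            integrand, 0, a, epsabs=epsabs, epsrel=epsrel, limit=limit,
        )
        tail_cos, _ = integrate.quad(
            f_cos, a, np.inf, weight="cos", wvar=w, epsabs=epsabs, limit=limit
        )
        tail_sin, _ = integrate.quad(
            f_sin, a, np.inf, weight="sin", wvar=w, epsabs=epsabs, limit=limit
        )
    val = head + tail_cos - tail_sin
    if not np.isfinite(val):
        raise RuntimeError("Imhof integration failed (non-finite integral)")
    p = 0.5 + val / np.pi
    flags: set[str] = set()
    if p <= 0:
        flags.add("imhof_nonpositive")
    return float(min(p, 1.0)), flags


def asymptotic_pvalue(
    numerator: float,
    lambdas: np.ndarray,
    df_term: int,
    truncation: float = WEIGHT_TRUNCATION,
) -> tuple[float, set[str]]:
    """Asymptotic p-value of the numerator trace under the weighted null.

    Builds the weighted chi-square null from the (truncated) residual
    covariance eigenvalues, evaluates the Farebrother engine, and falls back
    to Imhof (flagged ``"fallback_engine"``) if the series fails.
    """
    null = truncate_weights(
        WeightedChiSqNull(weights=np.asarray(lambdas, float), df=df_term),
        t=truncation,
    )
    try:
        return sf_farebrother(numerator, null)
    except SeriesDivergenceError:
        p, flags = sf_imhof(numerator, null)
        flags = set(flags) | {"fallback_engine"}
        if p <= 0:
            p = PRECISION_FLOOR
            flags.add("at_precision_limit")
        return p, flags
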