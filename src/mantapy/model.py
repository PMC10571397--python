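"""MANTA: asymptotic PERMANOVA test for user-defined MMR models.

The entry point is :class:`MantaModel`, a statsmodels-style model object
built from an n x q response matrix, a predictor table and a model formula.
``fit()`` returns a :class:`MantaResults` with one row per tested term:
degrees of freedom, the numerator trace (a sum of squares), the pseudo-F,
and the asymptotic p-value obtained from the weighted chi-square null whose
weights are the eigenvalues of the residual covariance of the full model.

A functional wrapper :func:`manta_test` mirrors the classical one-call
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, TermPartition, build_designs
from .mmr import FitResult, fit_mmr, trace_statistic
from .wchi2 import asymptotic_pvalue

__all__ = [
    "MantaModel",
    "MantaResults",
    "AssociationResult",
    "manta_test",
    "transform_responses",
]

#: below this n/q ratio the asymptotic p-value is flagged as conservative
LOW_N_OVER_Q = 20.0


def transform_responses(Y, kind: str = "none"):
    """Elementwise response transformation: ``none``, ``sqrt`` or ``log``.

    For multivariate proportions, ``sqrt`` makes the Euclidean trace test
    equivalent to PERMANOVA with the Hellinger distance.  Domain violations
    (negative values for sqrt, non-positive for log) raise with the
    offending cells listed.
    """
    arr = np.asarray(Y, dtype=float)
    if kind == "none":
        return Y
    if kind == "sqrt":
        bad = np.argwhere(arr < 0)
    elif kind == "log":
        bad = np.argwhere(arr <= 0)
    else:
        raise ValueError(f"unknown transform {kind!r}")
    if len(bad):
        cells = ", ".join(f"({i},{j})" for i, j in bad[:10])
        raise ValueError(
            f"{kind} transform domain violation at cells [{cells}]"
            + (" ..." if len(bad) > 10 else "")
        )
    out = np.sqrt(arr) if kind == "sqrt" else np.log(arr)
    if isinstance(Y, pd.DataFrame):
        return pd.DataFrame(out, index=Y.index, columns=Y.columns)
    return out


@dataclass
class AssociationResult:
    """Per-term test result."""

    term: str
    df: int
    sum_sq: float  # numerator trace tr{Y'(H-H0)Y}
    pseudo_F: float
    p_asymptotic: float
    flags: set = field(default_factory=set)


def _validate_Y(Y: np.ndarray) -> None:
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-d (n x q) array")
    if Y.shape[0] < 2 or Y.shape[1] < 1:
        raise ValueError("Y needs n >= 2 rows and q >= 1 columns")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains missing or non-finite entries")


class MantaModel:
    """Multivariate association model Y ~ formula.

    Parameters
    ----------
    Y : (n, q) array or DataFrame
        Quantitative response matrix (no missing values).
    data : DataFrame
        Predictor table, rows aligned with ``Y``.  Object/categorical/bool
        columns are treated as factors; numeric columns as continuous
        (override with ``categorical``).
    formula : str
        Right-hand side, e.g. ``"age + genotype + genotype:ancestry"``.
        Term order matters for Type I sums of squares.
    subset : str or list, optional
        Terms to test (default: all).  Typical GWAS usage tests only the
        genotype term, placed last in a Type I model.
    ss_type : {"I", "II", "III"}
    transform : {"none", "sqrt", "log"}
    """

    def __init__(
        self,
        Y,
        data: pd.DataFrame,
        formula: str,
        subset=None,
        ss_type: str = "I",
        transform: str = "none",
        categorical=None,
    ):
        Yt = transform_responses(Y, transform)
        self.trait_names = (
            list(Yt.columns)
            if isinstance(Yt, pd.DataFrame)
            else [f"y{j+1}" for j in range(np.asarray(Yt).shape[1])]
        )
        self.Y = np.asarray(Yt, dtype=float)
        _validate_Y(self.Y)
        if len(data) != self.Y.shape[0]:
            raise ValueError("Y and predictor table have different row counts")
        self.data = data.reset_index(drop=True)
        self.spec = ModelSpec.from_formula(formula, subset=subset)
        self.ss_type = str(ss_type).upper()
        self.transform = transform
        self.categorical = set(categorical or ())

    @classmethod
    def from_frames(cls, traits: pd.DataFrame, predictors: pd.DataFrame, formula, **kw):
        """Build from two aligned DataFrames (joined on their index)."""
        joined = traits.join(predictors, how="inner", lsuffix="_y")
        if len(joined) == 0:
            raise ValueError("no overlapping samples between traits and predictors")
        return cls(
            joined[traits.columns],
            joined[predictors.columns],
            formula,
            **kw,
        )

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    def partitions(self) -> list[TermPartition]:
        """One (full, reduced) design pair per testable term.

        Terms that are rank-deficient given their reduced model (df = 0)
        are skipped with a warning instead of aborting the fit.
        """
        import warnings

        from .design import ModelSpec as _Spec

        parts = []
        for term in self.spec.tested:
            try:
                parts.extend(
                    build_designs(
                        _Spec(self.spec.terms, [term]),
                        self.data,
                        ss_type=self.ss_type,
                        categorical=self.categorical,
                    )
                )
            except ValueError as err:
                if "rank-deficient" in str(err):
                    warnings.warn(
                        f"term {term.name!r} skipped: {err}", stacklevel=2
                    )
                else:
                    raise
        return parts

    def fit(self) -> "MantaResults":
        parts = self.partitions()
        common_flags: set[str] = set()
        if self.n / self.q < LOW_N_OVER_Q:
            common_flags.add("low_n_over_q")
        results = []
        fits = []
        for part in parts:
            fit = fit_mmr(self.Y, part)
            stat = trace_statistic(self.Y, part)
            p, flags = asymptotic_pvalue(stat.numerator, fit.lambdas, part.df_term)
            results.append(
                AssociationResult(
                    term=part.term,
                    df=part.df_term,
                    sum_sq=stat.numerator,
                    pseudo_F=stat.pseudo_F,
                    p_asymptotic=p,
                    flags=set(flags) | common_flags,
                )
            )
            fits.append(fit)
        return MantaResults(self, parts, fits, results)


class MantaResults:
    """Fitted results: per-term association table plus fit diagnostics."""

    def __init__(self, model, partitions, fits, results):
        self.model = model
        self.partitions = partitions
        self.fits: list[FitResult] = fits
        self.results: list[AssociationResult] = results

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "term": r.term,
                "df": r.df,
                "sum_sq": r.sum_sq,
                "pseudo_F": r.pseudo_F,
                "p_asymptotic": r.p_asymptotic,
                "flags": ",".join(sorted(r.flags)),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def pvalue(self, term: str) -> float:
        for r in self.results:
            if r.term == term:
                return r.p_asymptotic
        raise KeyError(f"term {term!r} was not tested")

    def __getitem__(self, term: str) -> AssociationResult:
        for r in self.results:
            if r.term == term:
                return r
        raise KeyError(term)

    def permutation_test(self, term: str, n_perm: int = 999, scheme=None, seed=None):
        """Permutation p-value for one term (see :mod:`mantapy.permutation`)."""
        from .permutation import PermutationScheme, permanova_perm

        if scheme is None:
            scheme = PermutationScheme(kind="free", n_perm=n_perm, seed=seed)
        return permanova_perm(
            self.model.Y,
            self.model.data,
            self.model.spec,
            term,
            scheme,
            ss_type=self.model.ss_type,
            categorical=self.model.categorical,
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "MANTA: asymptotic PERMANOVA test",
            "=" * 64,
            f"n = {m.n}, q = {m.q} traits, SS type {m.ss_type}, "
            f"transform = {m.transform}",
            f"model: ~ {' + '.join(t.name for t in m.spec.terms)}",
            "-" * 64,
            f"{'term':<16}{'df':>4}{'SS':>14}{'pseudo-F':>12}{'p':>12}  flags",
        ]
        for r in self.results:
            lines.append(
                f"{r.term:<16}{r.df:>4}{r.sum_sq:>14.4f}{r.pseudo_F:>12.4f}"
                f"{r.p_asymptotic:>12.3e}  {','.join(sorted(r.flags))}"
            )
        resid = self.fits[-1] if self.fits else None
        if resid is not None:
            lam = ", ".join(f"{v:.4g}" for v in resid.lambdas)
            lines += ["-" * 64, f"residual covariance eigenvalues: [{lam}]"]
        return "\n".join(lines)


def manta_test(
    Y,
    data: pd.DataFrame,
    formula: str,
    ss_type: str = "I",
    transform: str = "none",
    subset=None,
    categorical=None,
) -> list[AssociationResult]:
    """One-call interface: fit the model and return per-term results."""
    model = MantaModel(
        Y,
        data,
        formula,
        subset=subset,
        ss_type=ss_type,
        transform=transform,
        categorical=categorical,
    )
    return model.fit().results
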