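"""Design-matrix construction for multivariate multiple regression (MMR).

The test statistic compares the projection onto the column space of a full
design ``X`` with the projection onto a reduced design ``X0`` obtained by
dropping the columns of the term under test.  Which columns enter ``X`` and
``X0`` depends on the sums-of-squares type:

* Type I (sequential): terms enter in user order; the reduced model for term
  *k* contains the intercept plus all preceding terms.
* Type II: the full model contains every term except higher-order relatives
  of *k* (interactions involving all of *k*'s variables); the reduced model
  additionally drops *k*.
* Type III (marginal): the full model contains everything; the reduced model
  drops only *k*'s columns.

Categorical variables are expanded with full-rank treatment contrasts
(reference level = first level in sorted order).  Note that with treatment
coding, Type III tests of main effects in the presence of interactions are
coding-sensitive; Type I tests are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "TermPartition",
    "build_designs",
    "projection",
    "matrix_rank",
]


def _rank_tol(s: np.ndarray, shape: tuple[int, int]) -> float:
    # singular values below max(n, p)*eps*sigma_max are treated as zero
    return max(shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)


def matrix_rank(X: np.ndarray) -> int:
    """Numerical rank of a design matrix via SVD with a stated tolerance."""
    if X.size == 0:
        return 0
    s = np.linalg.svd(X, compute_uv=False)
    return int(np.sum(s > _rank_tol(s, X.shape)))


def orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of col(X) (n x rank), rank-revealing via SVD."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    return u[:, s > _rank_tol(s, X.shape)]


def projection(X: np.ndarray) -> np.ndarray:
    """Hat matrix H = X (X'X)^- X', via a rank-revealing orthonormal basis.

    Uses the pseudo-inverse implicitly, so rank-deficient designs are fine.
    H is symmetric and idempotent with trace(H) = rank(X).
    """
    Q = orth_basis(np.asarray(X, dtype=float))
    return Q @ Q.T


@dataclass(frozen=True)
class Term:
    """A single model term: one or more variable names crossed together."""

    variables: tuple[str, ...]

    @property
    def name(self) -> str:
        return ":".join(self.variables)

    @property
    def order(self) -> int:
        return len(self.variables)

    def is_higher_order_relative_of(self, other: "Term") -> bool:
        return self != other and set(other.variables) < set(self.variables)


@dataclass
class ModelSpec:
    """Ordered model specification: main effects, interactions, covariates.

    Parameters
    ----------
    terms : list of Term
        Model terms in user order (the intercept is always implicit).
    tested_subset : list of Term or None
        Terms whose parameters form the null hypothesis.  ``None`` tests
        every term.
    """

    terms: list[Term]
    tested_subset: list[Term] | None = None

    @classmethod
    def from_formula(cls, formula: str, subset: str | list[str] | None = None) -> "ModelSpec":
        """Parse a right-hand-side formula such as ``"A + B + A:B"``."""
        terms = []
        for raw in formula.replace("~", " ").split("+"):
            raw = raw.strip()
            if not raw or raw == "1":
                continue
            term = Term(tuple(v.strip() for v in raw.split(":")))
            if term in terms:
                raise ValueError(f"duplicated term {term.name!r} in formula")
            terms.append(term)
        if not terms:
            raise ValueError("empty model formula")
        tested = None
        if subset is not None:
            if isinstance(subset, str):
                subset = [s.strip() for s in subset.split(",") if s.strip()]
            tested = [Term(tuple(v.strip() for v in s.split(":"))) for s in subset]
            for t in tested:
                if t not in terms:
                    raise ValueError(f"tested term {t.name!r} not in model")
        return cls(terms=terms, tested_subset=tested)

    @property
    def tested(self) -> list[Term]:
        return self.tested_subset if self.tested_subset is not None else list(self.terms)


@dataclass
class TermPartition:
    """Full/reduced design pair for one tested term."""

    term: str
    X_full: np.ndarray
    X_reduced: np.ndarray
    rank_full: int
    rank_reduced: int

    Q_full: np.ndarray = field(repr=False, default=None)
    Q_reduced: np.ndarray = field(repr=False, default=None)

    @property
    def df_term(self) -> int:
        return self.rank_full - self.rank_reduced

    @property
    def n(self) -> int:
        return self.X_full.shape[0]

    @property
    def rank_resid(self) -> int:
        return self.n - self.rank_full


def _is_categorical(col: pd.Series) -> bool:
    return (
        isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == object
        or col.dtype == bool
        or pd.api.types.is_string_dtype(col)
    )


def code_variable(col: pd.Series, categorical: bool) -> np.ndarray:
    """Columns coding one variable: treatment contrasts or the raw values."""
    if not categorical:
        return np.asarray(col, dtype=float).reshape(-1, 1)
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) < 2:
        raise ValueError(
            f"categorical variable {col.name!r} has a single observed level"
        )
    vals = col.astype(str).to_numpy()
    # drop the first (sorted) level: full-rank treatment coding
    return np.column_stack([(vals == lv).astype(float) for lv in levels[1:]])


def term_columns(
    term: Term, data: pd.DataFrame, categorical: set[str]
) -> np.ndarray:
    """Coded columns for one term (interactions: columnwise products)."""
    blocks = []
    for v in term.variables:
        if v not in data.columns:
            raise KeyError(f"variable {v!r} not found in predictor table")
        blocks.append(code_variable(data[v], v in categorical))
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(data), -1)
    return out


def _validate_data(data: pd.DataFrame) -> None:
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing values in predictor columns {bad}")


def build_designs(
    spec: ModelSpec,
    data: pd.DataFrame,
    ss_type: str = "I",
    categorical: set[str] | list[str] | None = None,
) -> list[TermPartition]:
    """Build one (full, reduced) design pair per tested term.

    Parameters
    ----------
    ss_type : {"I", "II", "III"}
        Sums-of-squares type controlling the reduced design (see module
        docstring).  Type I results depend on the order of ``spec.terms``.
    categorical : collection of str, optional
        Names of variables to treat as categorical.  Non-numeric columns are
        always treated as categorical.
    """
    ss_type = str(ss_type).upper()
    if ss_type not in {"I", "II", "III"}:
        raise ValueError(f"unknown sums-of-squares type {ss_type!r}")
    _validate_data(data)
    cat = set(categorical or ())
    cat |= {c for c in data.columns if _is_categorical(data[c])}

    n = len(data)
    intercept = np.ones((n, 1))
    blocks = {t: term_columns(t, data, cat) for t in spec.terms}

    def assemble(terms: list[Term]) -> np.ndarray:
        cols = [intercept] + [blocks[t] for t in terms]
        return np.hstack(cols)

    partitions = []
    for t in spec.tested:
        if ss_type == "I":
            pre = spec.terms[: spec.terms.index(t)]
            full_terms = pre + [t]
            red_terms = pre
        elif ss_type == "II":
            keep = [
                u for u in spec.terms if not u.is_higher_order_relative_of(t)
            ]
            full_terms = keep
            red_terms = [u for u in keep if u != t]
        else:  # III
            full_terms = list(spec.terms)
            red_terms = [u for u in spec.terms if u != t]
        X = assemble(full_terms)
        X0 = assemble(red_terms)
        Q = orth_basis(X)
        Q0 = orth_basis(X0)
        part = TermPartition(
            term=t.name,
            X_full=X,
            X_reduced=X0,
            rank_full=Q.shape[1],
            rank_reduced=Q0.shape[1],
            Q_full=Q,
            Q_reduced=Q0,
        )
        if part.df_term == 0:
            raise ValueError(
                f"term {t.name!r} is rank-deficient given the reduced model "
                "(df = 0); it cannot be tested"
            )
        partitions.append(part)
    return partitions
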