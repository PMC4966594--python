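"""Additive model of glutamate production on process covariates.

The model is

    Y = c + s(X_1, m_1) + ... + s(X_p, m_p) + eps,   eps ~ N(0, sigma^2)

with each s a penalized cubic regression spline (knots at covariate
quantiles, curvature penalty) whose effective degrees of freedom m_i are
set by the smoothing parameter lambda_i.  Smoothing parameters minimize
the generalized cross-validation score

    GCV = N * RSS / (N - total_edf)^2

by coordinate-wise search over a log-spaced grid.  Each smooth is centred
(sum of fitted term values over the training rows is zero) so the
intercept c is identifiable as the response mean structure.  The ordinary
linear model is the special case where every term is an unpenalized
straight line (edf = 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = [
    "CubicSplineBasis",
    "SmoothTerm",
    "GAMFit",
    "build_basis",
    "fit_gam",
    "fit_glm",
    "predict",
    "gcv_score",
    "adjusted_r2",
    "term_significance",
    "significance_stars",
    "select_model",
    "residual_diagnostics",
]

_GAUSS_NODES = np.array([-1.0, 1.0]) / np.sqrt(3.0)  # 2-pt Gauss-Legendre


@dataclass(frozen=True)
class CubicSplineBasis:
    """Cubic B-spline basis on a covariate, with curvature penalty.

    The covariate is mapped affinely onto [0, 1] (so smoothing parameters
    are comparable across covariates of very different scales and fits are
    invariant to affine rescaling); interior knots sit at quantiles of the
    training values.  Outside the training range the basis extrapolates
    linearly (first-order Taylor expansion at the boundary).
    """

    lo: float
    hi: float
    knots: tuple  # full knot vector on the [0, 1] scale

    @property
    def ndim(self) -> int:
        return len(self.knots) - 4

    @classmethod
    def from_data(cls, x: np.ndarray, basis_dim: int = 10) -> "CubicSplineBasis":
        x = np.asarray(x, float)
        distinct = np.unique(x)
        if len(distinct) < 4:
            raise ValueError(
                f"need at least 4 distinct covariate values, got {len(distinct)}"
            )
        if len(distinct) < basis_dim:
            warnings.warn(
                f"basis_dim reduced from {basis_dim} to {len(distinct)} "
                "(fewer distinct covariate values)",
                stacklevel=2,
            )
            basis_dim = len(distinct)
        lo, hi = float(distinct[0]), float(distinct[-1])
        u = (distinct - lo) / (hi - lo)
        probs = np.linspace(0, 1, basis_dim - 2)[1:-1]
        interior = np.unique(np.quantile(u, probs))
        interior = interior[(interior > 1e-12) & (interior < 1 - 1e-12)]
        knots = np.concatenate([[0.0] * 4, interior, [1.0] * 4])
        return cls(lo, hi, tuple(knots))

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.lo) / (self.hi - self.lo)

    def _basis_splines(self) -> list[BSpline]:
        t = np.asarray(self.knots)
        eye = np.eye(self.ndim)
        return [BSpline(t, eye[k], 3, extrapolate=False) for k in range(self.ndim)]

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at raw covariate values (rows of the matrix)."""
        u = self._scale(x)
        t = np.asarray(self.knots)
        inside = np.clip(u, 0.0, 1.0)
        B = BSpline.design_matrix(inside, t, 3).toarray()
        below, above = u < 0.0, u > 1.0
        if below.any() or above.any():
            splines = self._basis_splines()
            for mask, edge in ((below, 0.0), (above, 1.0)):
                if not mask.any():
                    continue
                val = np.array([s(edge) for s in splines])
                der = np.array([s.derivative()(edge) for s in splines])
                B[mask] = val + np.outer(u[mask] - edge, der)
        return B

    def penalty(self) -> np.ndarray:
        """Exact integrated squared-second-derivative penalty matrix.

        Second derivatives of cubic splines are piecewise linear, so a
        2-point Gauss rule per inter-knot interval integrates their
        products exactly.  The null space contains constants and straight
        lines, which are therefore unpenalized.
        """
        t = np.asarray(self.knots)
        spans = np.unique(t)
        d2 = [s.derivative(2) for s in self._basis_splines()]
        S = np.zeros((self.ndim, self.ndim))
        for a, b in zip(spans[:-1], spans[1:]):
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            nodes = mid + half * _GAUSS_NODES
            D = np.array([f(nodes) for f in d2]).T  # (2, ndim)
            S += half * D.T @ D  # Gauss weights are 1
        return 0.5 * (S + S.T)


def build_basis(
    x: np.ndarray, basis_dim: int = 10
) -> tuple[np.ndarray, np.ndarray, CubicSplineBasis]:
    """Convenience wrapper: (design matrix, penalty matrix, basis object)."""
    basis = CubicSplineBasis.from_data(x, basis_dim)
    return basis.design(x), basis.penalty(), basis


def _helmert_complement(k: int) -> np.ndarray:
    """Orthonormal basis (k x k-1) of the complement of the ones direction.

    B-spline basis functions sum to one, so after column centring the
    all-equal coefficient direction maps every row to zero; projecting the
    centred block onto this complement removes that exact rank deficiency
    (it is the sum-to-zero identifiability constraint absorbed into the
    parameterization)."""
    from scipy.linalg import helmert

    return helmert(k).T


@dataclass
class SmoothTerm:
    """One fitted additive component.

    ``kind`` is ``"spline"`` for a penalized smooth or ``"linear"`` for the
    unpenalized straight-line special case.  ``col_means`` are the training
    column means subtracted for sum-to-zero centring; spline coefficients
    live in the constrained (k-1)-dimensional parameterization.
    """

    variable: str
    kind: str
    coefficients: np.ndarray
    col_means: np.ndarray
    edf: float
    lam: float
    basis: CubicSplineBasis | None = None

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.kind == "linear":
            return (x - self.col_means[0])[:, None]
        B = self.basis.design(x) - self.col_means
        return B @ _helmert_complement(self.basis.ndim)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Centred term value s(x) at raw covariate values."""
        return self.design(x) @ self.coefficients


@dataclass
class GAMFit:
    """A fitted additive model plus its summary statistics."""

    variables: list[str]
    intercept: float
    terms: list[SmoothTerm]
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    total_edf: float
    sigma2: float
    gcv: float
    adj_r2: float
    cov_unscaled: np.ndarray  # (X'X + S_lambda)^-1, intercept block first
    leverages: np.ndarray = None  # hat-matrix diagonal at the chosen lambdas
    selection_log: list = field(default_factory=list)
    # per-term centred training design blocks; kept in memory for the
    # fitted-value significance test but not serialized (reconstructable
    # from the training table via term.design)
    term_designs: list | None = None

    def predict(self, covariates) -> np.ndarray:
        return predict(self, covariates)

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def linear_coefficients(self) -> dict[str, float]:
        """Raw-scale intercept and slopes (linear/GLM fits only)."""
        if any(t.kind != "linear" for t in self.terms):
            raise ValueError("linear_coefficients requires an all-linear fit")
        slopes = {t.variable: float(t.coefficients[0]) for t in self.terms}
        raw_intercept = self.intercept - sum(
            t.coefficients[0] * t.col_means[0] for t in self.terms
        )
        return {"intercept": float(raw_intercept), **slopes}

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "intercept": self.intercept,
            "terms": [
                {
                    "variable": t.variable,
                    "kind": t.kind,
                    "coefficients": t.coefficients.tolist(),
                    "col_means": t.col_means.tolist(),
                    "edf": t.edf,
                    "lam": None if np.isinf(t.lam) else t.lam,
                    "basis": None
                    if t.basis is None
                    else {"lo": t.basis.lo, "hi": t.basis.hi, "knots": list(t.basis.knots)},
                }
                for t in self.terms
            ],
            "residuals": self.residuals.tolist(),
            "fitted": self.fitted.tolist(),
            "n": self.n,
            "total_edf": self.total_edf,
            "sigma2": self.sigma2,
            "gcv": self.gcv,
            "adj_r2": self.adj_r2,
            "cov_unscaled": self.cov_unscaled.tolist(),
            "leverages": None if self.leverages is None else self.leverages.tolist(),
            "selection_log": self.selection_log,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "GAMFit":
        terms = []
        for td in payload["terms"]:
            basis = None
            if td["basis"] is not None:
                basis = CubicSplineBasis(
                    td["basis"]["lo"], td["basis"]["hi"], tuple(td["basis"]["knots"])
                )
            terms.append(
                SmoothTerm(
                    variable=td["variable"],
                    kind=td["kind"],
                    coefficients=np.asarray(td["coefficients"], float),
                    col_means=np.asarray(td["col_means"], float),
                    edf=td["edf"],
                    lam=np.inf if td["lam"] is None else td["lam"],
                    basis=basis,
                )
            )
        return cls(
            variables=list(payload["variables"]),
            intercept=payload["intercept"],
            terms=terms,
            residuals=np.asarray(payload["residuals"], float),
            fitted=np.asarray(payload["fitted"], float),
            n=payload["n"],
            total_edf=payload["total_edf"],
            sigma2=payload["sigma2"],
            gcv=payload["gcv"],
            adj_r2=payload["adj_r2"],
            cov_unscaled=np.asarray(payload["cov_unscaled"], float),
            leverages=None
            if payload.get("leverages") is None
            else np.asarray(payload["leverages"], float),
            selection_log=payload.get("selection_log", []),
        )

    @classmethod
    def from_json(cls, path: str) -> "GAMFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting


def _column(table, var) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        if var not in table.columns:
            raise ValueError(f"covariate {var!r} missing from table")
        return table[var].to_numpy(float)
    if var not in table:
        raise ValueError(f"covariate {var!r} missing from table")
    return np.asarray(table[var], float)


class _Design:
    """Precomputed centred design blocks and penalties for one table."""

    def __init__(self, table, variables, basis_dim, linear=False, bases=None):
        y = _column(table, "glutamate")
        self.y = y
        self.n = len(y)
        if self.n < len(variables) + 2:
            raise ValueError(
                f"need at least {len(variables) + 2} rows, got {self.n}"
            )
        self.variables = list(variables)
        blocks, penalties, self.bases, self.col_means = [], [], [], []
        self.kinds = []
        for var in variables:
            x = _column(table, var)
            if np.ptp(x) == 0:
                raise ValueError(f"covariate {var!r} has zero variance")
            if linear:
                B = x[:, None]
                S = np.zeros((1, 1))
                self.bases.append(None)
                self.kinds.append("linear")
            else:
                basis = bases[var] if bases else CubicSplineBasis.from_data(x, basis_dim)
                B = basis.design(x)
                S = basis.penalty()
                self.bases.append(basis)
                self.kinds.append("spline")
            mu = B.mean(axis=0)
            self.col_means.append(mu)
            B = B - mu
            if not linear:
                Z = _helmert_complement(B.shape[1])
                B = B @ Z
                S = Z.T @ S @ Z
            blocks.append(B)
            penalties.append(S)
        self.blocks = blocks
        self.penalties = penalties
        dims = [b.shape[1] for b in blocks]
        self.slices = []
        start = 1  # column 0 is the intercept
        for d in dims:
            self.slices.append(slice(start, start + d))
            start += d
        X = np.concatenate([np.ones((self.n, 1))] + blocks, axis=1)
        self.X = X
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.tss = float(np.sum((y - y.mean()) ** 2))

    def with_response(self, y: np.ndarray) -> "_Design":
        """Shallow copy sharing the design blocks but with a new response
        (bootstrap refits only swap y, so X'X and penalties are reused)."""
        clone = object.__new__(_Design)
        clone.__dict__.update(self.__dict__)
        y = np.asarray(y, float)
        clone.y = y
        clone.Xty = self.X.T @ y
        clone.yty = float(y @ y)
        clone.tss = float(np.sum((y - y.mean()) ** 2))
        return clone

    def penalized_matrix(self, lam: np.ndarray) -> np.ndarray:
        A = self.XtX.copy()
        for lam_j, sl, S in zip(lam, self.slices, self.penalties):
            A[sl, sl] += lam_j * S
        return A

    def solve(self, lam: np.ndarray):
        """Return (beta, rss, edf_total, edf_terms, A_inv) for one lambda."""
        A = self.penalized_matrix(lam)
        try:
            cho = cho_factor(A, lower=True)
        except LinAlgError:
            raise ValueError(
                "singular design after centring; check for collinear "
                f"covariates among {self.variables}"
            ) from None
        beta = cho_solve(cho, self.Xty)
        rss = max(self.yty - beta @ (2 * self.Xty - self.XtX @ beta), 0.0)
        F = cho_solve(cho, self.XtX)
        diag = np.diag(F)
        edf_total = float(diag.sum())
        edf_terms = [float(diag[sl].sum()) for sl in self.slices]
        return beta, float(rss), edf_total, edf_terms, cho

    def gcv(self, lam: np.ndarray) -> float:
        _, rss, edf, _, _ = self.solve(lam)
        if edf >= self.n:
            return np.inf
        return self.n * rss / (self.n - edf) ** 2


_DEFAULT_GRID = np.logspace(-4, 6, 31)


def _optimize_lambdas(
    design: _Design,
    start: np.ndarray,
    grid: np.ndarray,
    max_sweeps: int = 8,
    rel_tol: float = 1e-6,
) -> np.ndarray:
    """Coordinate-wise GCV minimization over a log-spaced grid, followed by
    one local refinement pass between the best grid point's neighbours."""
    lam = start.copy()
    best = design.gcv(lam)
    p = len(lam)
    for _ in range(max_sweeps):
        prev = best
        for j in range(p):
            if np.isinf(lam[j]):
                continue
            trial = lam.copy()
            scores = np.empty(len(grid))
            for g, val in enumerate(grid):
                trial[j] = val
                scores[g] = design.gcv(trial)
            k = int(np.argmin(scores))
            if scores[k] < best:
                lam[j], best = grid[k], scores[k]
        if prev - best <= rel_tol * max(prev, 1e-300):
            break
    # refinement: a finer grid bracketing each term's current lambda
    ratio = grid[1] / grid[0] if len(grid) > 1 else 10.0
    for j in range(p):
        if np.isinf(lam[j]):
            continue
        local = lam[j] * ratio ** np.linspace(-1, 1, 9)
        trial = lam.copy()
        scores = np.empty(len(local))
        for g, val in enumerate(local):
            trial[j] = val
            scores[g] = design.gcv(trial)
        k = int(np.argmin(scores))
        if scores[k] < best:
            lam[j], best = local[k], scores[k]
    return lam


def _finalize(design: _Design, lam: np.ndarray) -> GAMFit:
    beta, rss, edf_total, edf_terms, cho = design.solve(lam)
    n = design.n
    if edf_total >= n:
        raise ValueError("model is over-saturated (total edf >= N)")
    fitted = design.X @ beta
    residuals = design.y - fitted
    sigma2 = rss / (n - edf_total)
    gcv = n * rss / (n - edf_total) ** 2
    adj_r2 = 1.0 - (rss / (n - edf_total)) / (design.tss / (n - 1))
    terms = []
    for j, var in enumerate(design.variables):
        sl = design.slices[j]
        terms.append(
            SmoothTerm(
                variable=var,
                kind=design.kinds[j],
                coefficients=beta[sl].copy(),
                col_means=design.col_means[j].copy(),
                edf=edf_terms[j],
                lam=float(lam[j]),
                basis=design.bases[j],
            )
        )
    A_inv = cho_solve(cho, np.eye(design.XtX.shape[0]))
    leverages = np.einsum("ij,jk,ik->i", design.X, A_inv, design.X)
    return GAMFit(
        variables=list(design.variables),
        intercept=float(beta[0]),
        terms=terms,
        residuals=residuals,
        fitted=fitted,
        n=n,
        total_edf=edf_total,
        sigma2=float(sigma2),
        gcv=float(gcv),
        adj_r2=float(adj_r2),
        cov_unscaled=A_inv,
        leverages=leverages,
        term_designs=[b.copy() for b in design.blocks],
    )


def fit_gam(
    table,
    variables: list[str],
    basis_dim: int = 10,
    lambdas: dict[str, float] | None = None,
    lambda_grid: np.ndarray | None = None,
    bases: dict[str, CubicSplineBasis] | None = None,
) -> GAMFit:
    """Fit the penalized additive model by GCV-optimized least squares.

    Parameters
    ----------
    table
        Training table (DataFrame or mapping of arrays) with a
        ``glutamate`` response column and one column per covariate.
    variables
        Covariate names entering as smooth terms.
    basis_dim
        Basis dimension per smooth (upper bound on each term's edf).
    lambdas
        Optional fixed smoothing parameters per variable; ``np.inf``
        forces a term to its unpenalized linear limit (edf 1), which makes
        the fit collapse exactly onto the ordinary linear model when all
        terms are infinite.  Missing entries are optimized.
    lambda_grid
        Search grid for the GCV optimization (defaults to 31 log-spaced
        points over 1e-4..1e6).
    bases
        Pre-built bases per variable (used when refitting bootstrap
        replicates on the same knots).
    """
    if not variables:
        raise ValueError("need at least one covariate")
    lambdas = lambdas or {}
    all_inf = len(lambdas) == len(variables) and all(
        np.isinf(lambdas.get(v, np.nan)) for v in variables
    )
    if all_inf:
        design = _Design(table, variables, basis_dim, linear=True)
        return _finalize(design, np.zeros(len(variables)))

    design = _Design(table, variables, basis_dim, bases=bases)
    p = len(variables)
    lam = np.ones(p)
    fixed = np.zeros(p, bool)
    for j, var in enumerate(variables):
        if var in lambdas:
            lam[j] = lambdas[var]
            fixed[j] = True
    if np.isinf(lam).any():
        raise ValueError(
            "per-term infinite lambda is only supported when every term is "
            "infinite (the pure linear model)"
        )
    if not fixed.all():
        grid = _DEFAULT_GRID if lambda_grid is None else np.asarray(lambda_grid)
        free = ~fixed
        lam_opt = _optimize_lambdas_masked(design, lam, grid, free)
        lam = lam_opt
    return _finalize(design, lam)


def _optimize_lambdas_masked(design, lam, grid, free_mask):
    if free_mask.all():
        return _optimize_lambdas(design, lam, grid)
    # optimize only the free coordinates
    lam = lam.copy()
    best = design.gcv(lam)
    for _ in range(8):
        prev = best
        for j in np.where(free_mask)[0]:
            trial = lam.copy()
            scores = [design.gcv(np.where(np.arange(len(lam)) == j, g, trial)) for g in grid]
            k = int(np.argmin(scores))
            if scores[k] < best:
                lam[j], best = grid[k], scores[k]
        if prev - best <= 1e-6 * max(prev, 1e-300):
            break
    return lam


def fit_glm(table, variables: list[str]) -> GAMFit:
    """Ordinary least squares on the raw covariates (every edf = 1)."""
    design = _Design(table, variables, basis_dim=0, linear=True)
    return _finalize(design, np.zeros(len(variables)))


def predict(fit: GAMFit, covariates) -> np.ndarray:
    """Evaluate c + sum of centred smooths at new covariate values.

    Covariates outside the training range are extrapolated linearly.
    """
    values = None
    for term in fit.terms:
        x = _column(covariates, term.variable)
        contrib = term.evaluate(x)
        values = contrib if values is None else values + contrib
    return fit.intercept + values


def gcv_score(fit: GAMFit) -> float:
    """GCV = N * RSS / (N - total_edf)^2 recomputed from the stored fit."""
    if fit.total_edf >= fit.n:
        raise ValueError("model is over-saturated (total edf >= N)")
    return fit.n * fit.rss / (fit.n - fit.total_edf) ** 2


def adjusted_r2(fit: GAMFit) -> float:
    if fit.total_edf >= fit.n:
        raise ValueError("model is over-saturated (total edf >= N)")
    y = fit.fitted + fit.residuals
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - (fit.rss / (fit.n - fit.total_edf)) / (tss / (fit.n - 1))


def term_significance(fit: GAMFit, table=None) -> dict[str, float]:
    """Wald-type test of each smooth's fitted function against zero.

    For term j with fitted values f_j = X_j beta_j over the training rows
    and covariance Cov(f_j) = X_j V_jj X_j' (V the posterior covariance of
    the coefficients), the statistic f' Cov^+ f -- the covariance
    pseudo-inverted at rank round(edf_j) -- is referred to an
    F(r, N - total_edf) distribution.  Testing in fitted-value space keeps
    the statistic well conditioned when penalization has shrunk most
    coefficient directions to near zero.  Degenerate all-zero terms report
    p = 1.
    """
    if fit.sigma2 <= 0:
        raise ValueError("sigma2 must be positive for significance testing")
    df_resid = max(fit.n - fit.total_edf, 1.0)
    pvals = {}
    start = 1
    for term in fit.terms:
        k = len(term.coefficients)
        V = fit.sigma2 * fit.cov_unscaled[start : start + k, start : start + k]
        start += k
        beta = term.coefficients
        if not np.any(beta):
            pvals[term.variable] = 1.0
            continue
        r = int(np.clip(np.ceil(term.edf), 1, k))
        # evaluate the term over its training design (kept on the fit, or
        # reconstructed from a supplied table after deserialization)
        if table is not None:
            Xj = term.design(_column(table, term.variable))
        elif fit.term_designs is not None:
            Xj = fit.term_designs[fit.variables.index(term.variable)]
        else:
            Xj = None
        if Xj is None:
            # coefficient-space fallback at the same rank
            M = V
            vec = beta
        else:
            M = Xj @ V @ Xj.T
            vec = Xj @ beta
        U, s, _ = np.linalg.svd(M, hermitian=True)
        s_inv = np.where(np.arange(len(s)) < r, 1.0 / np.maximum(s, 1e-300), 0.0)
        stat = float(vec @ (U * s_inv) @ (U.T @ vec))
        pvals[term.variable] = float(stats.f.sf(stat / r, r, df_resid))
    return pvals


def significance_stars(p: float) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def select_model(
    table,
    candidate_variables: list[str],
    alpha: float = 0.05,
    gcv_rel_tol: float = 0.05,
    prune_tol: float = 0.15,
    **fit_kwargs,
) -> GAMFit:
    """Backward elimination from the full candidate set.

    Two passes, mirroring the usual "highest adjusted R^2, lowest GCV,
    fewest significant components" model choice: first repeatedly drop the
    least-significant term with p > ``alpha`` as long as the GCV score does
    not rise by more than ``gcv_rel_tol`` (relative); then prune any
    remaining term that does not earn its keep predictively -- i.e. whose
    removal worsens GCV by less than ``prune_tol`` (relative).  The second
    pass guards against terms that fit sampling noise: such terms can reach
    nominal significance, but removing them costs almost no GCV, whereas
    removing a genuinely informative term degrades it severely.  The
    retained fit records the elimination steps in ``selection_log``.
    Raises if no candidate is informative.
    """
    if not candidate_variables:
        raise ValueError("need at least one candidate variable")
    current = list(candidate_variables)
    fit = fit_gam(table, current, **fit_kwargs)
    log = []
    while True:
        pvals = term_significance(fit)
        worst = max(current, key=lambda v: pvals[v])
        if pvals[worst] <= alpha:
            break
        if len(current) == 1:
            raise ValueError(
                "no informative covariate: all candidates eliminated"
            )
        trial_vars = [v for v in current if v != worst]
        trial = fit_gam(table, trial_vars, **fit_kwargs)
        if trial.gcv > fit.gcv * (1.0 + gcv_rel_tol):
            break
        log.append(
            {"dropped": worst, "p": pvals[worst], "gcv_before": fit.gcv, "gcv_after": trial.gcv}
        )
        current, fit = trial_vars, trial
    # GCV pruning pass
    improved = len(current) > 1
    while improved and len(current) > 1:
        improved = False
        pvals = term_significance(fit)
        for worst in sorted(current, key=lambda v: -pvals[v]):
            trial_vars = [v for v in current if v != worst]
            trial = fit_gam(table, trial_vars, **fit_kwargs)
            if trial.gcv <= fit.gcv * (1.0 + prune_tol):
                log.append(
                    {
                        "dropped": worst,
                        "p": pvals[worst],
                        "gcv_before": fit.gcv,
                        "gcv_after": trial.gcv,
                    }
                )
                current, fit = trial_vars, trial
                improved = True
                break
    fit.selection_log = log
    return fit


@dataclass
class Diagnostics:
    """Residual diagnostics bundle (computation only; plotting is left to
    the caller)."""

    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    measured: np.ndarray
    estimated: np.ndarray
    pearson_r: float
    rmse: float


def residual_diagnostics(fit: GAMFit, table=None, bins: int = 10) -> Diagnostics:
    """Model-checking quantities: normal Q-Q pairs, residual histogram,
    residual-vs-fitted and measured-vs-estimated pairs, Pearson r and RMSE.

    With ``table`` given, residuals are prediction errors on that table
    (e.g. the held-out batch); otherwise the training residuals are used.
    """
    if table is None:
        estimated = fit.fitted
        measured = fit.fitted + fit.residuals
    else:
        estimated = predict(fit, table)
        measured = _column(table, "glutamate")
    residuals = measured - estimated
    n = len(residuals)
    order = np.sort(residuals)
    probs = (np.arange(1, n + 1) - 0.5) / n
    theoretical = stats.norm.ppf(probs)
    counts, edges = np.histogram(residuals, bins=bins)
    if n > 1 and measured.std() > 0 and estimated.std() > 0:
        r = float(np.corrcoef(measured, estimated)[0, 1])
    else:
        r = np.nan
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return Diagnostics(
        qq_theoretical=theoretical,
        qq_sample=order,
        hist_counts=counts,
        hist_edges=edges,
        fitted=estimated,
        residuals=residuals,
        measured=measured,
        estimated=estimated,
        pearson_r=r,
        rmse=rmse,
    )
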