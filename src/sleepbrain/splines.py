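"""Penalized cubic regression splines and Gaussian additive mixed models.

This module implements the statistical engine the rest of the package is
built on:

* cubic regression spline bases with an exact integrated-squared-second-
  derivative penalty (``cr_basis``),
* design construction for plain smooths, varying-coefficient smooths
  (a smooth multiplied elementwise by another column) and tensor
  interaction smooths (``build_design``),
* mixed-model fitting by maximum marginal likelihood, with smoothing
  parameters and the participant random-intercept variance treated as
  variance components (``fit_gamm``),
* empirical-Bayes posterior simulation of the coefficients
  (``posterior_draws``),
* Wald-type tests of smooth terms with estimated degrees of freedom
  (``smooth_term_test``), likelihood-ratio tests between nested ML fits
  (``lrt``) and Benjamini-Hochberg FDR adjustment (``bh_adjust``).

Model and notation
------------------
For response y (length n), design X built from the terms, total penalty
S_lambda = sum_t lambda_t S_t and participant indicator Z,

    y = X beta + Z b + e,    b ~ N(0, sigma_b^2 I),   e ~ N(0, sigma^2 I),

with the penalized spline coefficients treated as Gaussian random effects
with precision lambda_t S_t / sigma^2.  Writing all penalized coefficients
(spline ranges and intercepts) as the "random" block with prior precision
S_b/sigma^2, the marginal log likelihood profiled over the unpenalized
coefficients and sigma^2 is, up to constants,

    -2 l_ML(lambda) = n log(2 pi Dp / n) + n
                      + log|Xr' Xr + S_b| - log|S_b|,

where Dp = min_beta ||y - X beta||^2 + beta' S_lambda beta is the
penalized deviance and Xr collects the penalized columns.  The outer
optimization runs L-BFGS-B on the log smoothing parameters; the inner
penalized least squares exploits the diagonal structure of the
random-intercept block, so each likelihood evaluation costs
O(p^2 m) for p spline/fixed columns and m participants.

The empirical-Bayes posterior of the coefficients at the optimum is
N(beta_hat, V_beta) with V_beta = sigma^2 (X'X + S_lambda)^{-1} restricted
to the spline/fixed block; sigma^2 is the usual RSS/(n - edf) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Smooth", "Tensor", "Linear", "cr_knots", "cr_basis", "cr_basis_at",
    "DesignInfo", "build_design", "design_matrix", "FitResult", "fit_gamm",
    "posterior_draws", "smooth_term_test", "lrt", "bh_adjust",
]

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# Cubic regression spline basis
# ---------------------------------------------------------------------------

def cr_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Knots at quantiles of the unique values of x.

    Repeated quantiles (heavily tied data) are resolved by spreading the
    offending knots by machine-epsilon-scale offsets so the spacing stays
    strictly positive.
    """
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(
            f"need at least k={k} distinct values to place knots, got {ux.size}")
    q = np.linspace(0.0, 1.0, k)
    knots = np.quantile(ux, q)
    # enforce strictly increasing spacing
    span = knots[-1] - knots[0]
    tiny = max(span, 1.0) * 1e3 * _EPS
    for i in range(1, k):
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + tiny
    return knots


def _cr_penalty_parts(knots: np.ndarray):
    """Return (F, S): F maps coefficients to second derivatives at the knots
    (natural boundary conditions), S is the integrated squared second
    derivative penalty D' B^{-1} D."""
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = 0.5 * (S + S.T)
    F = np.zeros((k, k))
    F[1:-1] = Binv_D  # second derivative is zero at the boundary knots
    return F, S


def cr_basis_at(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the cardinal cubic-regression-spline basis at x.

    The coefficients are the function values at the knots; within each
    interval the function is the natural interpolating cubic, and beyond
    the boundary knots it continues linearly.
    """
    x = np.asarray(x, dtype=float)
    k = knots.size
    F, _ = _cr_penalty_parts(knots)
    h = np.diff(knots)
    n = x.size
    X = np.zeros((n, k))

    xi = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, k - 2)
    hj = h[j]
    dm = knots[j + 1] - xi      # distance to the right knot
    dp = xi - knots[j]          # distance to the left knot
    am = dm / hj
    ap = dp / hj
    cm = (dm ** 3 / hj - hj * dm) / 6.0
    cp = (dp ** 3 / hj - hj * dp) / 6.0
    rows = np.arange(n)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]

    # linear extrapolation outside the knot range
    for side, idx in (("lo", x < knots[0]), ("hi", x > knots[-1])):
        if not np.any(idx):
            continue
        x0 = knots[0] if side == "lo" else knots[-1]
        jb = 0 if side == "lo" else k - 2
        hb = h[jb]
        # value row at the boundary knot
        val = np.zeros(k)
        val[jb if side == "lo" else jb + 1] = 1.0
        # derivative of the in-interval expression at the boundary knot
        der = np.zeros(k)
        der[jb] += -1.0 / hb
        der[jb + 1] += 1.0 / hb
        if side == "lo":
            dcm = (-3.0 * hb ** 2 / hb + hb) / 6.0   # d/dx cm at x = left knot
            dcp = (0.0 - hb) / 6.0                   # d/dx cp at x = left knot
        else:
            dcm = (0.0 + hb) / 6.0                   # at x = right knot: dm=0
            dcp = (3.0 * hb ** 2 / hb - hb) / 6.0
        der += dcm * F[jb] + dcp * F[jb + 1]
        X[idx] = val + (x[idx] - x0)[:, None] * der
    return X


def cr_basis(x: np.ndarray, k: int = 10, knots: np.ndarray | None = None):
    """Cubic regression spline basis and its curvature penalty.

    Returns ``(X, S, knots)`` with X of shape (n, k) and S the k x k
    symmetric positive semi-definite matrix such that ``beta @ S @ beta``
    equals the integral of the squared second derivative of the spline
    with coefficients beta.
    """
    if knots is None:
        knots = cr_knots(x, k)
    else:
        knots = np.asarray(knots, dtype=float)
    X = cr_basis_at(x, knots)
    _, S = _cr_penalty_parts(knots)
    return X, S, knots


# ---------------------------------------------------------------------------
# Term specifications and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Smooth:
    """A univariate penalized smooth, optionally a varying coefficient.

    With ``by`` set, the basis columns are multiplied elementwise by the
    by-variable, giving a coefficient that varies smoothly with ``var``.
    ``center=True`` absorbs a mean-zero constraint over the training rows
    so the term is identifiable alongside the intercept (and, for
    varying-coefficient terms, alongside the linear main effect of the
    by-variable, which should be supplied as a separate Linear term).
    """
    var: str
    k: int = 10
    by: str | None = None
    center: bool = True

    @property
    def name(self) -> str:
        return f"s({self.var})" if self.by is None else f"s({self.var}):{self.by}"


@dataclass(frozen=True)
class Tensor:
    """A bivariate tensor-product interaction smooth.

    Built as the row-wise Kronecker product of two marginal cubic
    regression spline bases with one curvature penalty per margin. The
    term is projected orthogonal (in the constraint sense) to the span of
    [1, basis(var1), basis(var2)] over the training rows, so a model
    containing this term strictly nests the additive model in the same
    marginals.
    """
    var1: str
    var2: str
    k1: int = 5
    k2: int = 5

    @property
    def name(self) -> str:
        return f"te({self.var1},{self.var2})"


@dataclass(frozen=True)
class Linear:
    """An unpenalized linear column (categorical columns are dummy-coded)."""
    var: str

    @property
    def name(self) -> str:
        return self.var


Term = Smooth | Tensor | Linear


@dataclass
class _TermInfo:
    term: Term
    sl: slice                      # columns in the assembled design
    penalties: list[np.ndarray] = field(default_factory=list)
    knots: np.ndarray | None = None
    knots2: np.ndarray | None = None
    Z: np.ndarray | None = None    # constraint null-space transform
    center: tuple[float, float] | None = None  # (mean, sd) for linear cols
    levels: list | None = None     # dummy levels for categorical linears

    @property
    def name(self) -> str:
        return self.term.name


@dataclass
class DesignInfo:
    X: np.ndarray
    terms: list[_TermInfo]
    columns: list[str]

    def term(self, name: str) -> _TermInfo:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _nullspace(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the null space of C (rows are constraints)."""
    C = np.atleast_2d(C)
    u, s, vt = np.linalg.svd(C, full_matrices=True)
    rank = int(np.sum(s > tol * max(s.max(initial=0.0), 1.0)))
    return vt[rank:].T


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n, ka = A.shape
    kb = B.shape[1]
    return (A[:, :, None] * B[:, None, :]).reshape(n, ka * kb)


def build_design(terms: Sequence[Term], df: pd.DataFrame,
                 intercept: bool = True) -> DesignInfo:
    """Assemble the model design matrix and penalty list from term specs.

    Continuous linear covariates are centered and scaled (the transform is
    recorded so prediction frames are treated identically); categorical
    linear covariates are dummy coded dropping the first level. Smooth
    terms use knots at quantiles of the training data.
    """
    n = len(df)
    blocks: list[np.ndarray] = []
    infos: list[_TermInfo] = []
    names: list[str] = []
    col = 0
    if intercept:
        blocks.append(np.ones((n, 1)))
        infos.append(_TermInfo(term=Linear("Intercept"), sl=slice(0, 1)))
        names.append("Intercept")
        col = 1

    for term in terms:
        if isinstance(term, Linear):
            v = df[term.var]
            if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) \
                    or v.dtype == bool:
                dummies = pd.get_dummies(v, drop_first=True, dtype=float)
                M = dummies.to_numpy()
                levels = list(dummies.columns)
                info = _TermInfo(term=term, sl=slice(col, col + M.shape[1]),
                                 levels=levels)
                names += [f"{term.var}[{lv}]" for lv in levels]
            else:
                x = v.to_numpy(dtype=float)
                mu, sd = float(x.mean()), float(x.std())
                sd = sd if sd > 0 else 1.0
                M = ((x - mu) / sd)[:, None]
                info = _TermInfo(term=term, sl=slice(col, col + 1),
                                 center=(mu, sd))
                names.append(term.var)
        elif isinstance(term, Smooth):
            x = df[term.var].to_numpy(dtype=float)
            # discretized covariates (e.g. half-hour sleep reports) may
            # offer fewer distinct values than the requested dimension
            k_eff = min(term.k, np.unique(x).size)
            if k_eff < 4:
                raise ValueError(
                    f"smooth of {term.var!r} needs >= 4 distinct values")
            B, S, knots = cr_basis(x, k_eff)
            if term.center:
                Zc = _nullspace(B.mean(axis=0)[None, :])
            else:
                Zc = np.eye(k_eff)
            M = B @ Zc
            if term.by is not None:
                M = M * df[term.by].to_numpy(dtype=float)[:, None]
            St = Zc.T @ S @ Zc
            info = _TermInfo(term=term, sl=slice(col, col + M.shape[1]),
                             penalties=[0.5 * (St + St.T)], knots=knots, Z=Zc)
            names += [f"{term.name}.{i}" for i in range(M.shape[1])]
        elif isinstance(term, Tensor):
            x1 = df[term.var1].to_numpy(dtype=float)
            x2 = df[term.var2].to_numpy(dtype=float)
            k1 = min(term.k1, np.unique(x1).size)
            k2 = min(term.k2, np.unique(x2).size)
            if min(k1, k2) < 4:
                raise ValueError(f"tensor term {term.name} needs >= 4 "
                                 "distinct values per margin")
            B1, S1, kn1 = cr_basis(x1, k1)
            B2, S2, kn2 = cr_basis(x2, k2)
            T = _row_kron(B1, B2)
            G = np.column_stack([np.ones(n), B1, B2])
            C = G.T @ T / n
            Zc = _nullspace(C)
            M = T @ Zc
            P1 = np.kron(S1, np.eye(k2))
            P2 = np.kron(np.eye(k1), S2)
            pen = [Zc.T @ P1 @ Zc, Zc.T @ P2 @ Zc]
            pen = [0.5 * (p + p.T) for p in pen]
            info = _TermInfo(term=term, sl=slice(col, col + M.shape[1]),
                             penalties=pen, knots=kn1, knots2=kn2, Z=Zc)
            names += [f"{term.name}.{i}" for i in range(M.shape[1])]
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown term type: {term!r}")
        blocks.append(M)
        infos.append(info)
        col += M.shape[1]

    X = np.hstack(blocks)
    # reject exactly duplicated columns (collinear design)
    if X.shape[1] > 1:
        norms = np.linalg.norm(X, axis=0)
        nz = norms > 0
        if np.any(~nz[1:]):
            raise ValueError("design contains an all-zero column")
    return DesignInfo(X=X, terms=infos, columns=names)


def design_matrix(info: DesignInfo, df: pd.DataFrame) -> np.ndarray:
    """Evaluate the design of a fitted model on new data.

    Uses the knots, constraint transforms and covariate scalings recorded
    at build time, so fitted coefficients apply directly.
    """
    n = len(df)
    X = np.zeros((n, info.p))
    for t in info.terms:
        term = t.term
        if isinstance(term, Linear):
            if term.var == "Intercept":
                X[:, t.sl] = 1.0
            elif t.levels is not None:
                v = df[term.var]
                M = np.zeros((n, len(t.levels)))
                for i, lv in enumerate(t.levels):
                    M[:, i] = (v == lv).to_numpy(dtype=float)
                X[:, t.sl] = M
            else:
                mu, sd = t.center
                X[:, t.sl] = ((df[term.var].to_numpy(dtype=float) - mu) / sd)[:, None]
        elif isinstance(term, Smooth):
            B = cr_basis_at(df[term.var].to_numpy(dtype=float), t.knots)
            M = B @ t.Z
            if term.by is not None:
                M = M * df[term.by].to_numpy(dtype=float)[:, None]
            X[:, t.sl] = M
        elif isinstance(term, Tensor):
            B1 = cr_basis_at(df[term.var1].to_numpy(dtype=float), t.knots)
            B2 = cr_basis_at(df[term.var2].to_numpy(dtype=float), t.knots2)
            X[:, t.sl] = _row_kron(B1, B2) @ t.Z
    return X


# ---------------------------------------------------------------------------
# Mixed-model fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted penalized-spline mixed model.

    ``beta`` and ``V_beta`` live in the original design coordinates of
    ``design`` (spline/fixed block only; participant intercept BLUPs are
    in ``ranef``).
    """
    design: DesignInfo
    beta: np.ndarray
    V_beta: np.ndarray
    lambdas: dict[str, list[float]]
    edf: dict[str, float]
    edf_total: float
    loglik_ml: float
    sigma2: float
    sigma2_b: float
    n: int
    groups: np.ndarray | None = None
    ranef: np.ndarray | None = None
    group_levels: np.ndarray | None = None

    def term_slice(self, name: str) -> slice:
        return self.design.term(name).sl

    def to_dict(self) -> dict:
        """JSON-serializable summary: coefficients, smoothing parameters,
        per-term edf, likelihood and variance components."""
        return {
            "beta": self.beta.tolist(),
            "columns": list(self.design.columns),
            "lambdas": self.lambdas,
            "edf": self.edf,
            "edf_total": self.edf_total,
            "loglik_ml": self.loglik_ml,
            "sigma2": self.sigma2,
            "sigma2_b": self.sigma2_b,
            "n": self.n,
        }

    def fitted_fixed(self, df: pd.DataFrame) -> np.ndarray:
        """Fixed-effect (population-level) predictions for new data."""
        return design_matrix(self.design, df) @ self.beta


class ConvergenceError(RuntimeError):
    pass


def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, levels = pd.factorize(np.asarray(groups))
    return codes.astype(np.int64), np.asarray(levels)


def fit_gamm(design: DesignInfo, y: np.ndarray,
             groups=None,
             fixed_lambdas: dict[str, list[float]] | None = None,
             tol: float = 1e-6,
             max_evals: int = 2000,
             start: np.ndarray | None = None) -> FitResult:
    """Fit the Gaussian additive mixed model by maximum marginal likelihood.

    Parameters
    ----------
    design : DesignInfo from build_design.
    y : response vector.
    groups : participant identifiers for the random intercept, or None.
    fixed_lambdas : optionally fix the smoothing parameters; maps term
        name to a list with one value per penalty of that term. The random
        intercept variance (if any) is still estimated.
    tol : convergence tolerance on the marginal log likelihood.
    start : optional start values for the log smoothing parameters.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = design.X
    p = X.shape[1]
    if n != X.shape[0]:
        raise ValueError("y length does not match design")

    # --- reparametrize each penalized term: null space -> fixed columns,
    #     range space -> penalized columns with transformed penalties
    fixed_cols: list[np.ndarray] = []
    fixed_src: list[tuple[int, np.ndarray]] = []   # (term index, transform)
    pen_blocks: list[dict] = []
    for ti, t in enumerate(design.terms):
        block = X[:, t.sl]
        if not t.penalties:
            fixed_cols.append(block)
            fixed_src.append((ti, np.eye(block.shape[1])))
            continue
        S_tot = sum(t.penalties)
        w, U = np.linalg.eigh(S_tot)
        thr = max(w.max(), 1.0) * 1e-9
        null = w < thr
        if np.any(null):
            fixed_cols.append(block @ U[:, null])
            fixed_src.append((ti, U[:, null]))
        Upos = U[:, ~null]
        if Upos.shape[1]:
            pen_blocks.append({
                "ti": ti,
                "U": Upos,
                "cols": block @ Upos,
                "S": [Upos.T @ S @ Upos for S in t.penalties],
            })

    Xf = np.hstack(fixed_cols) if fixed_cols else np.empty((n, 0))
    Xr = np.hstack([b["cols"] for b in pen_blocks]) if pen_blocks else np.empty((n, 0))
    pf, pr = Xf.shape[1], Xr.shape[1]
    W = np.hstack([Xf, Xr])
    ps = pf + pr
    if ps == 0:
        raise ValueError("empty design")

    # penalty layout within the Xr block
    pen_slices: list[slice] = []
    off = 0
    for b in pen_blocks:
        q = b["cols"].shape[1]
        pen_slices.append(slice(off, off + q))
        off += q
    n_pen = sum(len(b["S"]) for b in pen_blocks)

    has_groups = groups is not None
    if has_groups:
        codes, levels = _group_codes(groups)
        m = levels.size
        counts = np.bincount(codes, minlength=m).astype(float)
        # group sums: Z'W and Z'y
        ZtW = np.zeros((m, ps))
        np.add.at(ZtW, codes, W)
        Zty = np.bincount(codes, weights=y, minlength=m)
    else:
        codes = levels = None
        m = 0
        counts = np.zeros(0)
        ZtW = np.zeros((0, ps))
        Zty = np.zeros(0)

    A0 = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    B = ZtW.T  # ps x m

    def assemble_S(loglams: np.ndarray) -> np.ndarray:
        """Total penalty on the Xr block for the given log lambdas."""
        S = np.zeros((pr, pr))
        li = 0
        for b, sl in zip(pen_blocks, pen_slices):
            for Sk in b["S"]:
                S[sl, sl] += np.exp(loglams[li]) * Sk
                li += 1
        return S

    def logdet_S(loglams: np.ndarray, S: np.ndarray) -> float:
        if pr == 0:
            return 0.0
        w = np.linalg.eigvalsh(S)
        w = np.clip(w, 1e-300, None)
        return float(np.sum(np.log(w)))

    BIG = 1e10

    def criterion(theta: np.ndarray) -> float:
        loglams = theta[:n_pen]
        S = assemble_S(loglams)
        A = A0.copy()
        if pr:
            A[pf:, pf:] += S
        if has_groups:
            lam_b = np.exp(theta[-1])
            D = counts + lam_b
            BD = B / D
            Astar = A - BD @ B.T
            rhs = Wty - BD @ Zty
        else:
            lam_b = None
            D = None
            Astar = A
            rhs = Wty
        try:
            c, low = cho_factor(Astar, lower=True)
        except np.linalg.LinAlgError:
            return BIG
        beta_s = cho_solve((c, low), rhs)
        if has_groups:
            u = (Zty - B.T @ beta_s) / D
            Dp = yty - beta_s @ Wty - u @ Zty
        else:
            u = None
            Dp = yty - beta_s @ Wty
        Dp = max(Dp, n * 1e-12 * max(yty / max(n, 1), 1e-12))
        # log|G| over the random block (penalized splines + intercepts)
        if pr or has_groups:
            if has_groups:
                Ar = A0[pf:, pf:] + S if pr else np.empty((0, 0))
                Br = B[pf:, :]
                if pr:
                    Gs = Ar - (Br / D) @ Br.T
                    sign, ld = np.linalg.slogdet(Gs)
                    if sign <= 0:
                        return BIG
                    logdetG = float(np.sum(np.log(D))) + ld
                else:
                    logdetG = float(np.sum(np.log(D)))
                logdetSb = logdet_S(loglams, S) + m * float(theta[-1])
            else:
                Gs = A0[pf:, pf:] + S
                sign, ld = np.linalg.slogdet(Gs)
                if sign <= 0:
                    return BIG
                logdetG = ld
                logdetSb = logdet_S(loglams, S)
        else:
            logdetG = 0.0
            logdetSb = 0.0
        val = n * np.log(2.0 * np.pi * Dp / n) + n + logdetG - logdetSb
        return float(val)

    # --- assemble the hyperparameter vector
    free_pen = fixed_lambdas is None
    if not free_pen:
        fixed_ll = []
        for b in pen_blocks:
            name = design.terms[b["ti"]].name
            vals = fixed_lambdas.get(name)
            if vals is None:
                raise KeyError(f"fixed_lambdas missing term {name!r}")
            if np.isscalar(vals):
                vals = [vals] * len(b["S"])
            fixed_ll += [np.log(max(float(v), 1e-300)) for v in vals]
        fixed_ll = np.asarray(fixed_ll)

    n_free = (n_pen if free_pen else 0) + (1 if has_groups else 0)
    if n_free:
        if start is not None:
            x0 = np.asarray(start, dtype=float)
        else:
            x0 = np.zeros(n_free)
            if has_groups:
                # method-of-moments warm start for the intercept variance
                # ratio: the criterion is nearly flat in log lambda_b once
                # the intercepts are shrunk away, so a cold start can stall
                # on that plateau
                x0[-1] = _lambda_b_moment_start(W, y, codes, counts)

        def wrapped(xf: np.ndarray) -> float:
            if free_pen:
                theta = np.concatenate([xf[:n_pen],
                                        xf[n_pen:] if has_groups else []])
            else:
                theta = np.concatenate([fixed_ll, xf]) if has_groups else fixed_ll
            return criterion(theta)

        res = optimize.minimize(
            wrapped, x0, method="L-BFGS-B",
            bounds=[(-14.0, 18.0)] * n_free,
            options={"maxfun": max_evals, "ftol": tol / max(n, 1), "gtol": 1e-6},
        )
        if not np.isfinite(res.fun) or res.fun >= BIG:
            raise ConvergenceError("marginal likelihood optimization failed")
        xopt = res.x
        if free_pen:
            theta_opt = np.concatenate(
                [xopt[:n_pen], xopt[n_pen:] if has_groups else []])
        else:
            theta_opt = np.concatenate([fixed_ll, xopt]) if has_groups else fixed_ll
    else:
        theta_opt = fixed_ll if not free_pen else np.zeros(0)

    # --- final solve at the optimum
    loglams = theta_opt[:n_pen] if n_pen else np.zeros(0)
    S = assemble_S(loglams)
    A = A0.copy()
    if pr:
        A[pf:, pf:] += S
    if has_groups:
        lam_b = float(np.exp(theta_opt[-1]))
        D = counts + lam_b
        BD = B / D
        Astar = A - BD @ B.T
        rhs = Wty - BD @ Zty
    else:
        lam_b = np.inf
        Astar = A
        rhs = Wty
    c, low = cho_factor(Astar, lower=True)
    beta_s = cho_solve((c, low), rhs)
    E = cho_solve((c, low), np.eye(ps))  # (A - B D^-1 B')^{-1}
    if has_groups:
        u = (Zty - B.T @ beta_s) / D
        Dp = yty - beta_s @ Wty - u @ Zty
    else:
        u = None
        Dp = yty - beta_s @ Wty
    Dp = max(Dp, 1e-300)
    loglik = -0.5 * criterion(theta_opt)

    # effective degrees of freedom: diag(M^{-1} X'X)
    # W block: E @ A0 minus correction through the intercept block
    if has_groups:
        EB = E @ (B / D)
        diagW = np.einsum("ij,ji->i", E, A0) - np.einsum("ij,ij->i", EB, B)
        # intercept block of M^{-1} X'X:
        # diag_g = counts_g/D_g + BtEB_g*counts_g/D_g^2 - BtEB_g/D_g
        EBcols = E @ B                           # ps x m
        BtEB = np.einsum("ij,ij->j", B, EBcols)  # diag(B' E B)
        diagZ = -BtEB / D + (1.0 / D + BtEB / D ** 2) * counts
        edf_total = float(diagW.sum() + diagZ.sum())
    else:
        diagW = np.einsum("ij,ji->i", E, A0)
        edf_total = float(diagW.sum())

    rss = _rss(W, y, beta_s, codes, u)
    scale = rss / max(n - edf_total, 1.0)
    V_s = scale * E

    # --- map back to original design coordinates
    beta_orig = np.zeros(p)
    V_orig = np.zeros((p, p))
    # build the p x ps transform T such that beta_orig = T @ beta_s
    T = np.zeros((p, ps))
    colf = 0
    for ti, Uf in fixed_src:
        sl = design.terms[ti].sl
        q = Uf.shape[1]
        T[sl, colf:colf + q] = Uf
        colf += q
    colr = pf
    for b in pen_blocks:
        sl = design.terms[b["ti"]].sl
        q = b["U"].shape[1]
        T[sl, colr:colr + q] = b["U"]
        colr += q
    beta_orig = T @ beta_s
    V_orig = T @ V_s @ T.T

    # per-term edf
    edf = {}
    for ti, t in enumerate(design.terms):
        tot = 0.0
        ci = 0
        for tj, Uf in fixed_src:
            q = Uf.shape[1]
            if tj == ti:
                tot += diagW[ci:ci + q].sum()
            ci += q
        for b, slp in zip(pen_blocks, pen_slices):
            if b["ti"] == ti:
                tot += diagW[pf + slp.start: pf + slp.stop].sum()
        edf[t.name] = float(tot)

    lam_out: dict[str, list[float]] = {}
    li = 0
    for b in pen_blocks:
        name = design.terms[b["ti"]].name
        nlam = len(b["S"])
        lam_out[name] = [float(np.exp(loglams[li + j])) for j in range(nlam)]
        li += nlam

    sigma2_b = scale / lam_b if has_groups and np.isfinite(lam_b) else 0.0
    return FitResult(
        design=design, beta=beta_orig, V_beta=0.5 * (V_orig + V_orig.T),
        lambdas=lam_out, edf=edf, edf_total=edf_total,
        loglik_ml=float(loglik), sigma2=float(scale), sigma2_b=float(sigma2_b),
        n=n, groups=codes, ranef=u,
        group_levels=levels,
    )


def _lambda_b_moment_start(W, y, codes, counts) -> float:
    """Crude sigma^2 / sigma_b^2 estimate on residuals of a ridge solve."""
    ps = W.shape[1]
    A = W.T @ W + 1e-6 * np.trace(W.T @ W) / max(ps, 1) * np.eye(ps)
    try:
        beta = np.linalg.solve(A, W.T @ y)
    except np.linalg.LinAlgError:
        return 0.0
    r = y - W @ beta
    m = counts.size
    sums = np.bincount(codes, weights=r, minlength=m)
    sqsums = np.bincount(codes, weights=r * r, minlength=m)
    multi = counts >= 2
    if not multi.any():
        return 0.0
    within = float(np.sum(sqsums[multi] - sums[multi] ** 2 / counts[multi]))
    dof = float(np.sum(counts[multi] - 1))
    s2 = max(within / max(dof, 1.0), 1e-12)
    gmeans = sums / counts
    between = float(np.var(gmeans)) - s2 * float(np.mean(1.0 / counts))
    s2b = max(between, s2 * 1e-4)
    return float(np.clip(np.log(s2 / s2b), -8.0, 8.0))


def _rss(W, y, beta_s, codes, u) -> float:
    fitted = W @ beta_s
    if u is not None:
        fitted = fitted + u[codes]
    r = y - fitted
    return float(r @ r)


# ---------------------------------------------------------------------------
# Posterior simulation and tests
# ---------------------------------------------------------------------------

def posterior_draws(fit: FitResult, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo samples from the empirical-Bayes posterior of the
    coefficients, N(beta_hat, V_beta). Returns (n_draws, p)."""
    rng = np.random.default_rng(seed)
    V = fit.V_beta
    p = V.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(V + jitter * np.eye(p))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * max(np.trace(V) / p, 1e-30))
    else:
        raise np.linalg.LinAlgError("posterior covariance is not PSD")
    z = rng.standard_normal((n_draws, p))
    return fit.beta[None, :] + z @ L.T


def smooth_term_test(fit: FitResult, term: str):
    """Wald-type test of a smooth term with estimated degrees of freedom.

    The term's coefficient block is tested against zero using the
    empirical-Bayes covariance, with the rank of the pseudo-inverse set to
    the rounded edf of the term; the statistic is referred to an F
    distribution with (rank, n - edf_total) degrees of freedom.
    """
    sl = fit.term_slice(term)
    edf_t = fit.edf[term]
    if edf_t < 0.5:
        return np.nan, edf_t, np.nan
    b = fit.beta[sl]
    V = fit.V_beta[sl, sl]
    r = int(min(max(1, round(edf_t)), b.size))
    w, U = np.linalg.eigh(V)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    w = w[:r]
    U = U[:, :r]
    w = np.clip(w, 1e-300, None)
    T = float(((U.T @ b) ** 2 / w).sum())
    F = T / r
    df2 = max(fit.n - fit.edf_total, 1.0)
    p = float(stats.f.sf(F, r, df2))
    return F, float(edf_t), p


def lrt(fit_full: FitResult, fit_reduced: FitResult):
    """Likelihood-ratio test between nested maximum-likelihood fits.

    Degrees of freedom are the difference in effective degrees of freedom
    (excluding the random-intercept block, which is common to both
    models); the statistic is clamped at zero if the reduced model
    happens to attain a higher marginal likelihood.
    """
    if fit_full.n != fit_reduced.n:
        raise ValueError("fits use different numbers of rows; LRT invalid")
    stat = 2.0 * (fit_full.loglik_ml - fit_reduced.loglik_ml)
    clamped = False
    if stat < 0:
        stat = 0.0
        clamped = True
    df = sum(fit_full.edf.values()) - sum(fit_reduced.edf.values())
    df = max(df, 1e-8)
    if stat == 0.0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return float(stat), float(df), p, clamped


def bh_adjust(p_values, family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    adjusted p_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    ``family`` is a label used only in error messages; adjustment is
    always within the supplied vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(
            f"p values outside [0, 1] in family {family or '<unnamed>'}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
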