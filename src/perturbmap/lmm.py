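"""Restricted-maximum-likelihood linear mixed models with random intercepts.

The donor-heritability test refits the same mixed model under hundreds of
donor-label relabelings per (target, gene) pair, so the fit has to be cheap.
This module implements a profiled REML criterion for models of the form

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma^2 gamma_k I),
    eps ~ N(0, sigma^2 I),

where each ``Z_k`` is the indicator matrix of a categorical factor (guide,
cell line, donor, ...). Writing ``H = I + sum_k gamma_k Z_k Z_k'``, the
residual variance ``sigma^2`` profiles out in closed form and the Woodbury
identity reduces every likelihood evaluation to dense algebra in the total
number of factor levels ``q`` (typically < 40), independent of the number of
cells: only the cross-products ``Z'Z``, ``Z'X``, ``Z'y``, ``X'X``, ``X'y``,
``y'y`` are touched after construction.

The REML log-likelihood follows the standard convention (shared by lme4 and
statsmodels.MixedLM), so likelihood ratios are directly comparable:

    l_R = -1/2 [ (n-p) log(2 pi sigma^2_hat) + (n-p)
                 + log|H| + log|X' H^-1 X| ] ,
    sigma^2_hat = r' H^-1 r / (n - p).

Note the criterion omits the constant ``log|X'X|`` term some references add;
only differences of ``l_R`` at fixed ``X`` are used here, so the constant is
irrelevant for inference (a cross-check against MixedLM lives in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = ["LmmFit", "RandomInterceptLMM"]

_LOG_GAMMA_MIN = -30.0  # exp(-30) ~ 1e-13: numerically a zero component
_LOG_GAMMA_MAX = 12.0


@dataclass
class LmmFit:
    """Result of a REML fit.

    ``loglik`` is the restricted log-likelihood at the optimum; ``sigma2`` the
    residual variance; ``varcomp`` maps factor name to the variance of its
    random intercepts (``sigma^2 * gamma_k``); ``ranef`` maps factor name to
    the BLUPs of its levels, in the order of ``levels[name]``.
    """

    loglik: float
    sigma2: float
    varcomp: dict[str, float]
    beta: np.ndarray
    ranef: dict[str, np.ndarray] = field(default_factory=dict)
    levels: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True
    degenerate: bool = False


def _codes(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    return levels, codes


class RandomInterceptLMM:
    """REML fit of a Gaussian LMM whose random effects are all intercepts.

    Parameters
    ----------
    y : array of shape (n,)
        Response (per-cell perturbation effect, or normalized expression).
    X : array of shape (n, p)
        Fixed-effect design, including the intercept column.
    factors : dict of name -> array of shape (n,)
        Categorical labels defining one random-intercept term each.
    """

    def __init__(self, y, X, factors: dict[str, np.ndarray]):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent numbers of rows")
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("need more observations than fixed effects")
        self.names = list(factors)
        self.levels: dict[str, np.ndarray] = {}
        blocks = []
        self.block_slices: dict[str, slice] = {}
        start = 0
        for name in self.names:
            levs, codes = _codes(factors[name])
            self.levels[name] = levs
            Z = np.zeros((self.n, len(levs)))
            Z[np.arange(self.n), codes] = 1.0
            blocks.append(Z)
            self.block_slices[name] = slice(start, start + len(levs))
            start += len(levs)
        self.q = start
        Z = np.hstack(blocks) if blocks else np.zeros((self.n, 0))
        # cross-products: everything after this is O(q^3 + q^2 p) per eval
        self._ZtZ = Z.T @ Z
        self._ZtX = Z.T @ X
        self._Zty = Z.T @ y
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)
        self._ybar = float(y.mean())

    @classmethod
    def from_crossprods(
        cls,
        names: list[str],
        levels: dict[str, np.ndarray],
        ZtZ: np.ndarray,
        ZtX: np.ndarray,
        Zty: np.ndarray,
        XtX: np.ndarray,
        Xty: np.ndarray,
        yty: float,
        n: int,
        ybar: float,
    ) -> "RandomInterceptLMM":
        """Build a model directly from precomputed cross-products.

        Used by the permutation engine: relabeling donors only reshuffles
        line-level aggregates, so permuted models can be assembled without
        touching per-cell data.
        """
        self = cls.__new__(cls)
        self.n = n
        self.p = XtX.shape[0]
        self.names = list(names)
        self.levels = levels
        self.block_slices = {}
        start = 0
        for name in names:
            k = len(levels[name])
            self.block_slices[name] = slice(start, start + k)
            start += k
        self.q = start
        if ZtZ.shape != (self.q, self.q):
            raise ValueError("ZtZ shape inconsistent with levels")
        self._ZtZ = ZtZ
        self._ZtX = ZtX
        self._Zty = Zty
        self._XtX = XtX
        self._Xty = Xty
        self._yty = float(yty)
        self._ybar = float(ybar)
        return self

    # -- profiled REML criterion -------------------------------------------

    def _scale(self, gamma: np.ndarray) -> np.ndarray:
        s = np.empty(self.q)
        for name, g in zip(self.names, gamma):
            s[self.block_slices[name]] = np.sqrt(g)
        return s

    def _reml_pieces(self, gamma: np.ndarray, want_blup: bool = False):
        """Return (loglik, beta, sigma2, c, s) for variance ratios ``gamma``.

        ``c`` (only computed when ``want_blup``) solves
        (I + D Z'Z D) c = D Z'[y - X beta], which gives the BLUPs.
        """
        s = self._scale(gamma)
        A = self._ZtZ * np.outer(s, s)
        A.flat[:: self.q + 1] += 1.0
        try:
            L = cholesky(A, lower=True, check_finite=False)
        except LinAlgError:
            return None
        logdetH = 2.0 * np.log(np.diag(L)).sum()
        # H^-1 M = M - Zs (A^-1) Zs' M  computed through cross-products
        SZtX = s[:, None] * self._ZtX
        SZty = s * self._Zty
        W = solve_triangular(
            L, np.hstack([SZtX, SZty[:, None]]), lower=True, check_finite=False
        )
        WX, Wy = W[:, :-1], W[:, -1]
        XtHiX = self._XtX - WX.T @ WX
        XtHiy = self._Xty - WX.T @ Wy
        ytHiy = self._yty - float(Wy @ Wy)
        try:
            Lx = cholesky(XtHiX, lower=True, check_finite=False)
        except LinAlgError:
            return None
        beta = cho_solve((Lx, True), XtHiy, check_finite=False)
        quad = ytHiy - float(XtHiy @ beta)
        df = self.n - self.p
        if quad <= 0:
            quad = max(quad, 1e-300)
        sigma2 = quad / df
        logdetXtHiX = 2.0 * np.log(np.diag(Lx)).sum()
        ll = -0.5 * (
            df * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetH + logdetXtHiX
        )
        c = None
        if want_blup:
            resid_proj = SZty - SZtX @ beta
            c = cho_solve((L, True), resid_proj, check_finite=False)
        return ll, beta, sigma2, c, s

    def loglik(self, gamma) -> float:
        pieces = self._reml_pieces(np.asarray(gamma, dtype=float))
        return -np.inf if pieces is None else pieces[0]

    def loglik_and_grad(self, gamma):
        """REML loglik and its analytic gradient wrt the variance ratios.

        Uses the envelope theorem for the profiled beta and sigma^2:
        dl/dg_k = -1/2 [ tr(Z_k' H^-1 Z_k) - tr(B^-1 X'H^-1 Z_k Z_k' H^-1 X)
                         - ||Z_k' H^-1 r||^2 / sigma^2 ],  B = X' H^-1 X.
        """
        gamma = np.asarray(gamma, dtype=float)
        s = self._scale(gamma)
        A = self._ZtZ * np.outer(s, s)
        A.flat[:: self.q + 1] += 1.0
        try:
            L = cholesky(A, lower=True, check_finite=False)
        except LinAlgError:
            return -np.inf, np.zeros(len(gamma))
        logdetH = 2.0 * np.log(np.diag(L)).sum()
        Cs = s[:, None] * self._ZtZ  # Zs' Z
        SZtX = s[:, None] * self._ZtX
        SZty = s * self._Zty
        # H^-1 pushed through cross-products
        AiCs = cho_solve((L, True), Cs, check_finite=False)
        AiX = cho_solve((L, True), SZtX, check_finite=False)
        Aiy = cho_solve((L, True), SZty, check_finite=False)
        ZHZ = self._ZtZ - Cs.T @ AiCs
        ZHX = self._ZtX - Cs.T @ AiX
        ZHy = self._Zty - Cs.T @ Aiy
        XtHiX = self._XtX - SZtX.T @ AiX
        XtHiy = self._Xty - SZtX.T @ Aiy
        ytHiy = self._yty - float(SZty @ Aiy)
        try:
            Lx = cholesky(XtHiX, lower=True, check_finite=False)
        except LinAlgError:
            return -np.inf, np.zeros(len(gamma))
        beta = cho_solve((Lx, True), XtHiy, check_finite=False)
        Q = ytHiy - float(XtHiy @ beta)
        df = self.n - self.p
        Q = max(Q, 1e-300)
        sigma2 = Q / df
        logdetB = 2.0 * np.log(np.diag(Lx)).sum()
        ll = -0.5 * (df * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdetH + logdetB)
        u = ZHy - ZHX @ beta  # Z' H^-1 r
        E = solve_triangular(Lx, ZHX.T, lower=True, check_finite=False)  # p x q
        e2 = (E**2).sum(axis=0)
        diagZHZ = np.diag(ZHZ)
        u2 = u**2
        grad = np.empty(len(gamma))
        for i, name in enumerate(self.names):
            b = self.block_slices[name]
            grad[i] = -0.5 * (
                diagZHZ[b].sum() - e2[b].sum() - u2[b].sum() / sigma2
            )
        return ll, grad

    def fit_grad(self, start, ftol: float = 1e-9) -> float:
        """Fast REML maximization with the analytic gradient (L-BFGS-B on
        log variance ratios); returns only the optimal loglik.

        Used inside permutation loops where thousands of refits are needed
        and only the likelihood ratio matters.
        """
        k = len(self.names)

        def negf(t):
            g = np.exp(np.clip(t, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
            ll, grad = self.loglik_and_grad(g)
            if not np.isfinite(ll):
                return np.inf, np.zeros(k)
            return -ll, -grad * g

        t0 = np.log(np.clip(np.broadcast_to(np.atleast_1d(start), k), 1e-12, None))
        res = minimize(
            negf, t0, jac=True, method="L-BFGS-B",
            bounds=[(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX)] * k,
            options={"ftol": ftol, "maxiter": 200},
        )
        return -res.fun

    def fit(self, starts=None, fatol: float = 1e-8, maxfev: int | None = None) -> LmmFit:
        """Maximize the REML criterion over the variance ratios.

        ``starts`` is an iterable of starting gamma vectors (scalars are
        broadcast); the default tries 0.1 and 1.0 for robustness. A single
        warm start with a looser ``fatol`` is noticeably faster inside
        permutation loops.
        """
        k = len(self.names)
        yvar = (self._yty - self.n * self._ybar**2) / max(self.n - 1, 1)
        if yvar < 1e-12:
            # constant response: all components zero, flagged degenerate
            return LmmFit(
                loglik=np.nan,
                sigma2=0.0,
                varcomp={n: 0.0 for n in self.names},
                beta=np.zeros(self.p),
                levels=self.levels,
                converged=False,
                degenerate=True,
            )
        if k == 0:
            ll, beta, sigma2, _, _ = self._reml_pieces(np.zeros(0))
            return LmmFit(ll, sigma2, {}, beta, levels=self.levels)

        def neg(t):
            g = np.exp(np.clip(t, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX))
            ll = self.loglik(g)
            return np.inf if not np.isfinite(ll) else -ll

        if starts is None:
            starts = (0.1, 1.0)
        best = None
        options = {"xatol": 1e-4, "fatol": fatol, "maxiter": 400 * k}
        if maxfev is not None:
            options["maxfev"] = maxfev
        for s0 in starts:
            t0 = np.log(np.clip(np.broadcast_to(np.atleast_1d(s0), k), 1e-12, None))
            res = minimize(neg, t0, method="Nelder-Mead", options=options)
            if best is None or res.fun < best.fun:
                best = res
        t = np.clip(best.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
        gamma = np.exp(t)
        # snap numerically-zero components to exactly zero if that helps
        g0 = np.where(t <= _LOG_GAMMA_MIN + 1e-9, 0.0, gamma)
        if not np.array_equal(g0, gamma) and self.loglik(g0) >= -best.fun:
            gamma = g0
        ll, beta, sigma2, c, s = self._reml_pieces(gamma, want_blup=True)
        varcomp = {
            name: float(sigma2 * g) for name, g in zip(self.names, gamma)
        }
        ranef = {
            name: s[self.block_slices[name]] * c[self.block_slices[name]]
            for name in self.names
        }
        return LmmFit(
            loglik=float(ll),
            sigma2=float(sigma2),
            varcomp=varcomp,
            beta=beta,
            ranef=ranef,
            levels=self.levels,
            converged=bool(best.success),
        )
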