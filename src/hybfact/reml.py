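"""Restricted-maximum-likelihood machinery for linear mixed models.

All mixed models in this package share the same shape:

    y = X b + u_1 + ... + u_K + e,   u_k ~ N(0, sigma2_k K_k),  e ~ N(0, sigma2_e I)

where each ``K_k`` is an n x n covariance kernel on the observations (for
classical combining-ability BLUP these are incidence products Z Z'; for
GBLUP they are marker-derived relationship kernels).  The residual variance
is profiled out and the REML criterion is maximized over the K log
variance ratios gamma_k = sigma2_k / sigma2_e with Nelder-Mead, which is
derivative-free and robust at the zero-variance boundary (gamma -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

# log-ratio box: gamma below exp(-25) is a numerical zero, above exp(25)
# the residual is effectively zero
_LOG_GAMMA_BOUND = 25.0
_ZERO_VARIANCE = 1e-12


class ConvergenceError(RuntimeError):
    """REML maximization failed; carries the last criterion value."""

    def __init__(self, message: str, last_nll: float | None = None):
        super().__init__(message)
        self.last_nll = last_nll


@dataclass
class RemlFit:
    """REML estimates and the pieces needed for BLUP and prediction."""

    beta: np.ndarray          # GLS fixed effects
    sigma2: np.ndarray        # one variance per kernel
    sigma2_e: float
    gammas: np.ndarray        # sigma2 / sigma2_e
    vinv_resid: np.ndarray    # V0^{-1} (y - X beta) with V0 = I + sum gamma_k K_k
    nll: float                # -2 * restricted log-likelihood (up to constant)
    n_evals: int
    degenerate: bool = False  # constant-response convention applied

    def kernel_blup(self, k: int, cross_cov: np.ndarray) -> np.ndarray:
        """BLUP of component k at targets with covariance ``cross_cov``.

        ``cross_cov`` holds Cov(target, y) in units of K_k, i.e. rows of
        A Z' for effect-level BLUPs or K* rows for new observations.
        """
        return self.gammas[k] * (cross_cov @ self.vinv_resid)


def _criterion(
    log_gammas: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
) -> tuple[float, dict]:
    """-2 restricted log-likelihood with sigma2_e profiled out."""
    n, p = X.shape
    gammas = np.exp(np.clip(log_gammas, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
    V0 = np.eye(n)
    for g, K in zip(gammas, kernels):
        V0 += g * K
    try:
        cho = linalg.cho_factor(V0, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, {}
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ViX = linalg.cho_solve(cho, X, check_finite=False)
    Viy = linalg.cho_solve(cho, y, check_finite=False)
    XtViX = X.T @ ViX
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, {}
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    resid = y - X @ beta
    quad = float(resid @ linalg.cho_solve(cho, resid, check_finite=False))
    if quad <= 0:
        return np.inf, {}
    nll = logdet_V0 + logdet_XtViX + (n - p) * np.log(quad)
    aux = {"gammas": gammas, "beta": beta, "resid": resid, "quad": quad, "cho": cho}
    return nll, aux


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    max_evals: int = 1000,
    tol: float = 1e-8,
    extra_starts: int = 1,
) -> RemlFit:
    """Maximize the restricted likelihood over the kernel variance ratios.

    Several Nelder-Mead starts are used (equal-ratio start plus spread-out
    ones) and the best optimum is kept; convergence requires at least one
    start to terminate within ``max_evals`` criterion evaluations at
    relative tolerance ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if n <= p:
        raise ValueError("more fixed effects than observations")
    nk = len(kernels)

    # constant-response convention: everything at the zero lower bound
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.allclose(y, X @ beta_ols, atol=1e-12 * max(1.0, np.abs(y).max())):
        return RemlFit(
            beta=beta_ols,
            sigma2=np.full(nk, _ZERO_VARIANCE),
            sigma2_e=_ZERO_VARIANCE,
            gammas=np.ones(nk),
            vinv_resid=np.zeros(n),
            nll=-np.inf,
            n_evals=0,
            degenerate=True,
        )

    def objective(t: np.ndarray) -> float:
        return _criterion(t, y, X, kernels)[0]

    starts = [np.zeros(nk)]
    rng = np.random.default_rng(0)
    for s in range(extra_starts):
        starts.append(rng.uniform(-3.0, 3.0, nk))

    best = None
    last_nll = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": max_evals,
                "xatol": 1e-6,
                "fatol": tol * max(1.0, abs(objective(x0))),
            },
        )
        last_nll = res.fun
        if np.isfinite(res.fun) and res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError(
            f"REML did not converge within {max_evals} evaluations", last_nll=last_nll
        )

    nll, aux = _criterion(best.x, y, X, kernels)
    gammas = aux["gammas"]
    sigma2_e = aux["quad"] / (n - p)
    sigma2 = gammas * sigma2_e
    # snap numerically-zero ratios to the boundary
    at_zero = gammas <= np.exp(-_LOG_GAMMA_BOUND + 1e-9)
    sigma2[at_zero] = 0.0
    vinv_resid = linalg.cho_solve(aux["cho"], aux["resid"], check_finite=False)
    return RemlFit(
        beta=aux["beta"],
        sigma2=sigma2,
        sigma2_e=sigma2_e,
        gammas=gammas,
        vinv_resid=vinv_resid,
        nll=nll,
        n_evals=best.nfev,
    )


def reml_grid_profile(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    log_gamma_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile the REML criterion on a dense grid of log variance ratios.

    Returns the grid point minimizing the criterion and the full criterion
    array (shape ``(len(grid),) * len(kernels)``).  Intended as a slow,
    derivative-free cross-check of :func:`fit_reml`.
    """
    shape = (len(log_gamma_grid),) * len(kernels)
    values = np.full(shape, np.inf)
    for idx in np.ndindex(shape):
        t = np.array([log_gamma_grid[i] for i in idx])
        values[idx] = _criterion(t, y, X, kernels)[0]
    best_idx = np.unravel_index(np.argmin(values), shape)
    best = np.array([log_gamma_grid[i] for i in best_idx])
    return best, values
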