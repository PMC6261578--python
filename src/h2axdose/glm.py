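"""Identity-link Poisson scoring for focus-count regression.

The counts Y_i are modelled with mean m_i = sum_j X_ij beta_j where the
design matrix already carries the cell numbers (X rows are
n_i * [1, x_i, ...]), so beta lives on the yield scale (foci/cell and
foci/cell/Gy). The score equations

    sum_i X_i (Y_i - m_i) / m_i = 0

do not involve the dispersion, so the quasi-Poisson point estimates equal
the plain Poisson ones; only the standard errors are later inflated by
sqrt(phi).

Solved by Fisher scoring, which for the identity link is iteratively
reweighted least squares with working response Y and weights 1/m. Steps are
damped (halved) whenever they would drive a fitted mean non-positive,
because the score divides by m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, DegenerateFitError

__all__ = ["IdentityPoissonFit", "fit_identity_poisson", "poisson_deviance"]

MAX_ITER = 500
TOL = 1e-8


@dataclass(frozen=True)
class IdentityPoissonFit:
    """Raw output of the identity-link Poisson fit (count scale)."""

    params: np.ndarray           # yield-scale coefficients
    cov_poisson: np.ndarray      # inverse Fisher information (phi = 1)
    fitted: np.ndarray           # fitted count means m_i
    deviance: float
    n_iter: int

    @property
    def se_poisson(self) -> np.ndarray:
        """Uncorrected Poisson SEs: sqrt of the inverse-information diagonal."""
        return np.sqrt(np.diag(self.cov_poisson))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum[y log(y/mu) - (y - mu)], with 0 log 0 = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary least squares of counts on the design; nudged to positive means."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.all(X @ beta > 0):
        return beta
    # flat-curve fallback: match the overall mean through the first column
    beta = np.zeros(X.shape[1])
    col0 = X[:, 0]
    beta[0] = max(y.sum(), 0.5) / col0.sum()
    return beta


def fit_identity_poisson(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> IdentityPoissonFit:
    """Fit counts ``y`` with mean ``X @ beta`` by damped Fisher scoring.

    Raises
    ------
    ConvergenceError
        if the relative parameter change has not dropped below ``tol``
        within ``max_iter`` iterations (or no admissible damped step exists).
    DegenerateFitError
        if any fitted mean is non-positive at convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("design/response shape mismatch")

    beta = _start_values(X, y)
    mu = X @ beta
    if np.any(mu <= 0):
        raise DegenerateFitError("no positive-mean starting values found")

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / mu
        XtW = X.T * w
        info = XtW @ X
        try:
            beta_ls = np.linalg.solve(info, XtW @ y)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc

        step = beta_ls - beta
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            mu_cand = X @ cand
            if np.all(mu_cand > 0):
                break
            t *= 0.5
        else:
            raise ConvergenceError("step halving failed to keep fitted means positive")

        rel = np.max(np.abs(t * step) / np.maximum(np.abs(beta), 1e-12))
        beta, mu = cand, mu_cand
        if rel < tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(f"no convergence after {max_iter} iterations")
    if np.any(mu <= 0):
        raise DegenerateFitError("fitted mean non-positive at convergence")

    w = 1.0 / mu
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    return IdentityPoissonFit(
        params=beta,
        cov_poisson=cov,
        fitted=mu,
        deviance=poisson_deviance(y, mu),
        n_iter=it,
    )
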