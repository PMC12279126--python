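"""Cox proportional-hazards core: Breslow partial likelihood and solvers.

All higher-level survival fits in the package (univariate and multivariate
Cox models, the L1-penalized signature selection) are built on the functions
here.  The tie convention is Breslow throughout: tied event times share one
risk set and the log-denominator is counted once per event.

Conventions
-----------
* ``time`` is the observed follow-up time (months), ``event`` is 1 for an
  observed event (complete radiographic healing) and 0 for censoring.
* The penalized objective used by the L1 path is the *averaged* negative
  partial log-likelihood, ``-pll(beta)/n + lam * ||beta||_1``, matching the
  scaling under which ``lam_max = max_j |grad_j(0)| / n`` shrinks every
  coefficient to zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConvergenceError(RuntimeError):
    """Raised when a partial-likelihood solver fails to converge."""


def _as_sorted(time, event, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (len(time) == len(event) == X.shape[0]):
        raise ValueError("time, event and X must have matching lengths")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="mergesort")
    return time[order], event[order], X[order], order


def cox_loglik(beta, time, event, X, order=1, presorted=False):
    """Breslow partial log-likelihood and derivatives.

    Parameters
    ----------
    order : {0, 1, 2}
        0 returns pll only; 1 adds the gradient; 2 adds the (negative)
        Hessian of the *negative* log-likelihood, i.e. the observed
        information matrix.

    Returns
    -------
    pll, (grad), (info)
    """
    if not presorted:
        time, event, X, _ = _as_sorted(time, event, X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n, p = X.shape
    eta = X @ beta
    c = eta.max() if n else 0.0
    w = np.exp(eta - c)

    # reverse cumulative sums: S0[i] = sum_{j >= i} w_j over the time-sorted
    # sample, so S0 at the first index of a tied block is the Breslow risk-set
    # denominator for that event time.
    S0 = np.cumsum(w[::-1])[::-1]
    uniq_t, first = np.unique(time, return_index=True)
    gidx = np.searchsorted(uniq_t, time)
    d = np.bincount(gidx[event == 1], minlength=len(uniq_t))
    keep = d > 0
    if not keep.any():
        raise ValueError("no events in the data (all censored)")
    du = d[keep].astype(float)
    S0u = S0[first][keep]

    ev = event == 1
    pll = float(eta[ev].sum() - (du * (np.log(S0u) + c)).sum())
    if order == 0:
        return pll

    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    m = S1[first][keep] / S0u[:, None]
    grad = X[ev].sum(axis=0) - (du[:, None] * m).sum(axis=0)
    if order == 1:
        return pll, grad

    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    S2u = S2[first][keep] / S0u[:, None, None]
    info = np.einsum("u,ujk->jk", du, S2u) - np.einsum("u,uj,uk->jk", du, m, m)
    return pll, grad, info


def newton_cox(time, event, X, max_iter=100, tol=1e-9):
    """Unpenalized Cox fit by Newton-Raphson with step halving.

    Returns ``(beta, cov, pll, trace)`` where ``cov`` is the inverse observed
    information and ``trace`` records (iteration, pll, max|grad|).
    """
    time, event, X, _ = _as_sorted(time, event, X)
    n, p = X.shape
    beta = np.zeros(p)
    pll, grad, info = cox_loglik(beta, time, event, X, order=2, presorted=True)
    trace = [(0, pll, float(np.abs(grad).max()))]
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it}; trace={trace}"
            ) from exc
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            new_pll = cox_loglik(cand, time, event, X, order=0, presorted=True)
            if new_pll >= pll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError(f"step halving failed; trace={trace}")
        beta = cand
        pll, grad, info = cox_loglik(beta, time, event, X, order=2, presorted=True)
        trace.append((it, pll, float(np.abs(grad).max())))
        if np.abs(grad).max() < tol or np.abs(step * delta).max() < 1e-12:
            cov = np.linalg.inv(info)
            return beta, cov, pll, trace
    raise ConvergenceError(f"Newton-Raphson did not converge; trace={trace}")


@dataclass
class BaselineCumHaz:
    """Breslow baseline cumulative hazard as a right-continuous step function."""

    times: np.ndarray
    cumhaz: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)


def breslow_baseline(time, event, X, beta) -> BaselineCumHaz:
    """Breslow estimator of the baseline cumulative hazard."""
    time, event, X, _ = _as_sorted(time, event, X)
    eta = X @ np.atleast_1d(beta)
    c = eta.max()
    w = np.exp(eta - c)
    S0 = np.cumsum(w[::-1])[::-1]
    uniq_t, first = np.unique(time, return_index=True)
    gidx = np.searchsorted(uniq_t, time)
    d = np.bincount(gidx[event == 1], minlength=len(uniq_t))
    keep = d > 0
    increments = d[keep] / (S0[first][keep] * np.exp(c))
    return BaselineCumHaz(uniq_t[keep], np.cumsum(increments))


# ---------------------------------------------------------------------------
# L1-penalized path (FISTA with backtracking)
# ---------------------------------------------------------------------------

def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def kkt_violation(beta, lam, time, event, X, presorted=False):
    """Max KKT violation of the averaged L1-penalized Cox objective."""
    n = X.shape[0] if X.ndim == 2 else len(X)
    _, grad = cox_loglik(beta, time, event, X, order=1, presorted=presorted)
    g = -grad / n  # gradient of the averaged negative log-likelihood
    beta = np.atleast_1d(beta)
    viol = np.where(
        beta != 0,
        np.abs(g + lam * np.sign(beta)),
        np.maximum(np.abs(g) - lam, 0.0),
    )
    return float(viol.max())


def lambda_max(time, event, X):
    """Smallest penalty at which all coefficients are exactly zero."""
    time, event, X, _ = _as_sorted(time, event, X)
    n = X.shape[0]
    _, grad = cox_loglik(np.zeros(X.shape[1]), time, event, X, order=1,
                         presorted=True)
    return float(np.abs(grad).max() / n)


def lasso_cox_fit(time, event, X, lam, beta0=None, max_iter=5000, tol=1e-8):
    """Solve the L1-penalized Cox problem at one penalty value.

    FISTA (accelerated proximal gradient) with backtracking line search on
    the averaged negative Breslow partial log-likelihood.  Convergence is
    declared on the KKT conditions (max violation <= ``tol``).
    """
    time, event, X, _ = _as_sorted(time, event, X)
    n, p = X.shape

    def f_and_g(b):
        pll, grad = cox_loglik(b, time, event, X, order=1, presorted=True)
        return -pll / n, -grad / n

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    y = beta.copy()
    t_mom = 1.0
    L = 1.0
    fy, gy = f_and_g(y)
    for it in range(max_iter):
        while True:
            cand = _soft(y - gy / L, lam / L)
            diff = cand - y
            f_cand = -cox_loglik(cand, time, event, X, order=0, presorted=True) / n
            if f_cand <= fy + gy @ diff + 0.5 * L * diff @ diff + 1e-14:
                break
            L *= 2.0
            if L > 1e12:
                raise ConvergenceError("FISTA backtracking diverged")
        beta_new = cand
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = beta_new + (t_mom - 1.0) / t_new * (beta_new - beta)
        beta, t_mom = beta_new, t_new
        fy, gy = f_and_g(y)
        L = max(L / 1.5, 1e-6)
        if it % 10 == 9 or np.abs(beta_new - cand).max() == 0:
            if kkt_violation(beta, lam, time, event, X, presorted=True) <= tol:
                return beta
    if kkt_violation(beta, lam, time, event, X, presorted=True) <= 10 * tol:
        return beta
    raise ConvergenceError(f"FISTA did not reach KKT tolerance {tol} at lam={lam}")


def lasso_cox_path(time, event, X, lambda_grid=None, n_lambdas=50,
                   lambda_min_ratio=0.05, tol=1e-8):
    """Coefficient path of the L1-penalized Cox model.

    Returns ``(lambdas, B)`` with ``B`` of shape (n_lambdas, p), computed
    from the largest penalty down with warm starts.  ``X`` is used as given;
    standardize beforehand if coefficients should be comparable.
    """
    time, event, X, _ = _as_sorted(time, event, X)
    if lambda_grid is None:
        lmax = lambda_max(time, event, X)
        lambda_grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    else:
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    B = np.zeros((len(lambda_grid), X.shape[1]))
    beta = None
    for k, lam in enumerate(lambda_grid):
        beta = lasso_cox_fit(time, event, X, lam, beta0=beta, tol=tol)
        B[k] = beta
    return lambda_grid, B
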