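"""Independent quasi-Newton solve of the maxent objective.

Used only to *verify* the coordinate-descent fitter on small instances: the
L1 objective is rewritten with λ = u − v (u, v ≥ 0), which is smooth with
box constraints, and handed to L-BFGS-B with an analytic gradient. This
shares no code path with the production fitter beyond the feature matrices,
so agreement between the two is evidence of correctness, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

__all__ = ["fit_maxent_lbfgs"]


def fit_maxent_lbfgs(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta0: float = 1.0,
    beta: np.ndarray | None = None,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Return (lambda, objective) minimizing the L1-regularized Gibbs loss.

    ``beta`` overrides the default β_j = max(beta0·s_j/√m, 1e-4) so the
    exact same penalty as a production fit can be checked.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    m, J = P.shape
    a = P.mean(axis=0)
    if beta is None:
        s = P.std(axis=0, ddof=0)
        beta = np.maximum(beta0 * s / np.sqrt(m), 1e-4)
    beta = np.asarray(beta, dtype=float)

    def fun(z):
        u, v = z[:J], z[J:]
        lam = u - v
        eta = B @ lam
        f = -a @ lam + logsumexp(eta) + beta @ (u + v)
        w = softmax(eta)
        e = w @ B
        g_lam = e - a
        return f, np.concatenate([g_lam + beta, -g_lam + beta])

    z0 = np.zeros(2 * J)
    res = minimize(
        fun, z0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        options={"maxiter": 10_000, "ftol": tol, "gtol": 1e-10},
    )
    lam = res.x[:J] - res.x[J:]
    lam = _newton_polish(lam, a, B, beta)
    obj = float(-a @ lam + logsumexp(B @ lam) + beta @ np.abs(lam))
    return lam, obj


def _newton_polish(lam, a, B, beta, max_steps: int = 50):
    """Sharpen the solution to near machine precision.

    On the active set fixed by the quasi-Newton solution the objective is
    smooth (|λ_j| = sign_j·λ_j), so full Newton steps on that reduced
    problem converge quadratically. Steps are damped to stay within the
    orthant; coordinates driven to zero leave the active set.
    """
    lam = lam.copy()
    # treat near-zero coordinates as inactive
    lam[np.abs(lam) < 1e-10] = 0.0
    for _ in range(max_steps):
        active = np.flatnonzero(lam != 0.0)
        if active.size == 0:
            break
        sign = np.sign(lam[active])
        eta = B @ lam
        w = np.exp(eta - eta.max())
        w /= w.sum()
        Ba = B[:, active]
        e = w @ Ba
        grad = e - a[active] + beta[active] * sign
        cov = (Ba * w[:, None]).T @ Ba - np.outer(e, e)
        try:
            step = np.linalg.solve(cov + 1e-12 * np.eye(active.size), grad)
        except np.linalg.LinAlgError:
            break
        # damp so no active coordinate crosses zero
        new = lam[active] - step
        crossing = np.sign(new) * sign < 0
        scale = 1.0
        if crossing.any():
            scale = 0.99 * np.min(np.abs(lam[active][crossing] / step[crossing]))
        lam[active] = lam[active] - scale * step
        lam[np.abs(lam) < 1e-12] = 0.0
        if scale == 1.0 and np.abs(step).max() < 1e-13:
            break
    return lam
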