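"""Independent oracles used only by the test suite.

These deliberately avoid the package's optimizer code paths: the
grid-search oracle evaluates the cost by brute force over a dense k grid,
and the direct-weight oracle minimizes the reverse-KL-regularized cost
over all N weights at once (softmax parameterization) — the classical
formulation the k-vector method is meant to reproduce at matched
reweighting strength.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from ure import Ensemble, ObservableSet, cost, ensemble_preservation


def grid_search_k(
    theta: float,
    prior: Ensemble,
    obs: ObservableSet,
    k_lo: float = 0.0,
    k_hi: float = 20.0,
    step: float = 1e-3,
) -> tuple[np.ndarray, float]:
    """Dense 1-D grid search over a scalar k (M must be 1)."""
    assert obs.n_observables == 1
    ks = np.arange(k_lo, k_hi + step, step)
    costs = [cost(np.array([k]), theta, prior, obs) for k in ks]
    i = int(np.argmin(costs))
    return np.array([ks[i]]), float(costs[i])


def grid_search_k_2d(
    theta: float,
    prior: Ensemble,
    obs: ObservableSet,
    k_lo: float = -2.0,
    k_hi: float = 12.0,
    n: int = 141,
) -> tuple[np.ndarray, float]:
    """Dense 2-D grid search (M must be 2), refined once around the best cell."""
    assert obs.n_observables == 2
    best_k, best_c = None, np.inf
    lo = np.array([k_lo, k_lo], dtype=float)
    hi = np.array([k_hi, k_hi], dtype=float)
    for _ in range(3):  # coarse-to-fine refinement
        g0 = np.linspace(lo[0], hi[0], n)
        g1 = np.linspace(lo[1], hi[1], n)
        for a in g0:
            for b in g1:
                c = cost(np.array([a, b]), theta, prior, obs)
                if c < best_c:
                    best_c, best_k = c, np.array([a, b])
        span = (hi - lo) / (n - 1) * 4
        lo, hi = best_k - span, best_k + span
    return best_k, float(best_c)


def direct_weight_optimum(
    theta_w: float, prior: Ensemble, obs: ObservableSet
) -> Ensemble:
    """Global minimizer of theta_w * D_KL(w||w0) + chi^2(w) over the simplex.

    The objective is convex in w (chi^2 is a convex quadratic of the
    weighted averages, reverse KL is convex), so the softmax-parameterized
    L-BFGS solution from w0 is the global optimum up to tolerance.
    """
    w0 = prior.weights
    logw0 = np.log(w0)
    C, o, s = obs.calc_matrix, obs.exp_value, obs.sigma
    M = obs.n_observables

    def f(a: np.ndarray):
        a = a - a.max()
        e = np.exp(a)
        w = e / e.sum()
        resid = (o - C.T @ w) / s
        chi = float(np.mean(resid**2))
        dkl = float(np.sum(w * (np.log(w) - logw0)))
        gw = theta_w * ((np.log(w) - logw0) + 1.0) - (2.0 / M) * (C @ (resid / s))
        ga = w * (gw - float(w @ gw))
        return theta_w * dkl + chi, ga

    res = minimize(
        f, logw0.copy(), jac=True, method="L-BFGS-B",
        options={"maxiter": 3000, "ftol": 1e-14, "gtol": 1e-12},
    )
    a = res.x - res.x.max()
    e = np.exp(a)
    return Ensemble(e / e.sum(), prior.conformer_ids)


def direct_weights_at_ep(
    target_ep: float, prior: Ensemble, obs: ObservableSet, n_bisect: int = 45
) -> Ensemble:
    """Tune the direct optimizer's strength until its e.p. matches target_ep."""
    lo, hi = -9.0, 9.0
    w = prior
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        w = direct_weight_optimum(float(np.exp(mid)), prior, obs)
        if ensemble_preservation(w, prior) < target_ep:
            lo = mid
        else:
            hi = mid
    return w
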