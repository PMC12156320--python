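"""Umbrella Refinement of Ensembles: the k-vector reweighting method.

Instead of optimizing all N conformer weights directly, the refinement
optimizes a small vector k of per-observable force-constant-like
parameters of an umbrella-sampling-style bias potential

    V_bias(k, t) = sum_i (1/2) k_i ((O_i^exp - O_i^calc(t)) / sigma_i)^2

(reduced units, k_B T = 1; only k / k_B T is identifiable).  The reweighted
ensemble follows from the umbrella-reweighting identity

    w_t(k) = w0_t exp(-V_bias(k, t)) / Z,

so k = 0 reproduces the prior exactly and weights stay strictly positive
on the prior's support for any finite k.  The k-vector is chosen to
minimize the regularized cost

    cost(k) = theta * D_KL(k) + chi^2(k),

balancing divergence from the prior (maximum-entropy regularization)
against agreement with experiment.  The forward Kullback-Leibler direction
D_KL(w0 || w(k)) is the default: it is mode-covering, keeping probability
on every region the prior populates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .ensemble import Ensemble, InvalidWeightsError, ObservableSet

__all__ = [
    "KLDirection",
    "RefinementResult",
    "deviation_matrix",
    "bias_potential",
    "weights_from_k",
    "chi2",
    "kl_forward",
    "kl_reverse",
    "cost",
    "optimize_k",
    "regularization_path",
]

KLDirection = Literal["forward", "reverse"]


def _require_preconditioned(obs: ObservableSet) -> None:
    if obs.noe_mask.any() and not obs.noe_preconditioned:
        raise ValueError(
            "NOE upper bounds must be preconditioned to r^-6 space before "
            "refinement; see ure.io.precondition_noe"
        )


def deviation_matrix(
    obs: ObservableSet, *, noe_one_sided: bool = True
) -> np.ndarray:
    """Squared normalized deviations d2[t, i] = ((exp_i - calc[t, i]) / sigma_i)^2.

    For NOE upper bounds (preconditioned to r^-6 space) with
    ``noe_one_sided=True``, a conformer that satisfies the bound
    (r_t <= bound, i.e. r_t^-6 >= bound^-6) contributes zero: satisfying
    an upper bound is not a disagreement, so it must not be penalized by
    the bias potential.
    """
    _require_preconditioned(obs)
    dev = (obs.exp_value[None, :] - obs.calc_matrix) / obs.sigma[None, :]
    d2 = dev**2
    if noe_one_sided:
        noe = obs.noe_mask
        if noe.any():
            # bound^-6 - r^-6 > 0  <=>  r > bound  <=>  violated
            violated = obs.calc_matrix[:, noe] < obs.exp_value[None, noe]
            d2[:, noe] = np.where(violated, d2[:, noe], 0.0)
    return d2


def bias_potential(k: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Per-conformer umbrella bias V[t] = sum_i (1/2) k_i d2[t, i], in k_B T."""
    kv = np.atleast_1d(np.asarray(k, dtype=float))
    d2 = np.atleast_2d(np.asarray(d2, dtype=float))
    if d2.shape[1] != kv.size:
        raise ValueError(
            f"k has length {kv.size} but d2 has {d2.shape[1]} observables"
        )
    if not np.all(np.isfinite(kv)):
        raise ValueError("k must be finite")
    return 0.5 * (d2 @ kv)


def weights_from_k(
    k: np.ndarray, prior: Ensemble, d2: np.ndarray
) -> Ensemble:
    """Map a k-vector to reweighted ensemble weights w_t = w0_t e^{-V_t} / Z.

    Normalization is log-sum-exp stabilized, so arbitrarily large bias
    potentials cannot overflow.  Zero-prior conformers stay at zero; all
    others stay strictly positive for finite k.  k = 0 returns the prior
    exactly.
    """
    V = bias_potential(k, d2)
    w0 = prior.weights
    if w0.size != V.size:
        raise ValueError("prior length does not match deviation matrix")
    with np.errstate(divide="ignore"):
        loga = np.where(w0 > 0, np.log(np.where(w0 > 0, w0, 1.0)) - V, -np.inf)
    m = loga.max()
    if not np.isfinite(m):
        raise InvalidWeightsError("prior has no positive weights")
    u = np.exp(loga - m)
    return Ensemble(u / u.sum(), prior.conformer_ids)


def _residuals(
    weights: np.ndarray, obs: ObservableSet, *, noe_one_sided: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized residuals per observable and the active-term mask.

    The residual is (exp_i - <calc_i>_w) / sigma_i.  One-sided NOE upper
    bounds (in r^-6 space, exp = bound^-6) are clipped at zero when
    satisfied: <r^-6> >= bound^-6 means the averaged distance is within
    the bound.  The mask marks terms with nonzero chi^2 gradient.
    """
    means = obs.calc_matrix.T @ weights
    resid = (obs.exp_value - means) / obs.sigma
    active = np.ones(obs.n_observables, dtype=bool)
    if noe_one_sided:
        noe = obs.noe_mask
        if noe.any():
            satisfied = resid[noe] <= 0
            r = resid[noe]
            r[satisfied] = 0.0
            resid[noe] = r
            a = active[noe]
            a[satisfied] = False
            active[noe] = a
    return resid, active


def chi2(
    weights: Ensemble | np.ndarray,
    obs: ObservableSet,
    *,
    noe_one_sided: bool = True,
) -> float:
    """Reduced chi-squared between experiment and weighted ensemble averages.

    chi^2 = (1/M) sum_i ((O_i^exp - <O_i>_w) / sigma_i)^2, where <O_i>_w is
    the linear average of the (preconditioned) calculated column.  NOE
    upper bounds contribute only when violated (one-sided, default).
    """
    _require_preconditioned(obs)
    w = weights.weights if isinstance(weights, Ensemble) else np.asarray(weights, float)
    if w.size != obs.n_conformers:
        raise ValueError("weights length does not match calc_matrix rows")
    resid, _ = _residuals(w, obs, noe_one_sided=noe_one_sided)
    return float(np.mean(resid**2))


def _as_weights(e: Ensemble | np.ndarray) -> np.ndarray:
    return e.weights if isinstance(e, Ensemble) else np.asarray(e, dtype=float)


def kl_forward(
    prior: Ensemble | np.ndarray, proposal: Ensemble | np.ndarray
) -> float:
    """Forward Kullback-Leibler divergence D_KL(P || Q), P = prior, in nats.

    The forward direction is mode-covering: it is infinite wherever the
    proposal abandons mass the prior holds (this cannot happen for
    proposals produced by :func:`weights_from_k` at finite k).
    """
    p = _as_weights(prior)
    q = _as_weights(proposal)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def kl_reverse(
    proposal: Ensemble | np.ndarray, prior: Ensemble | np.ndarray
) -> float:
    """Reverse Kullback-Leibler divergence D_KL(Q || P), Q = proposal, in nats.

    The reverse direction is mode-seeking; it also underlies the
    ensemble-preservation diagnostic.
    """
    return kl_forward(proposal, prior)


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of one URE optimization.

    Attributes
    ----------
    k_opt
        Optimized per-observable force constants (k_B T per squared
        normalized deviation).
    weights_opt
        Reweighted ensemble.
    chi2_init, chi2_opt
        Reduced chi-squared before / after refinement.
    dkl_forward, dkl_reverse
        KL divergences between prior and optimized weights, nats.
    cost
        theta * D_KL + chi^2 at the optimum (in the configured direction).
    ensemble_preservation
        Percent of the prior ensemble effectively retained (100 = unchanged).
    theta
        Regularization strength used.
    converged
        False if the optimizer hit its iteration budget.
    n_iterations
        Optimizer iterations performed.
    """

    k_opt: np.ndarray
    weights_opt: Ensemble
    chi2_init: float
    chi2_opt: float
    dkl_forward: float
    dkl_reverse: float
    cost: float
    ensemble_preservation: float
    theta: float
    converged: bool
    n_iterations: int

    @property
    def has_negative_k(self) -> bool:
        """Negative force constants are admissible but physically suspect."""
        return bool(np.any(self.k_opt < 0))


def _cost_and_grad(
    k: np.ndarray,
    theta: float,
    w0: np.ndarray,
    logw0: np.ndarray,
    d2: np.ndarray,
    obs: ObservableSet,
    kl_direction: KLDirection,
    noe_one_sided: bool,
) -> tuple[float, np.ndarray]:
    """Cost theta*D_KL + chi^2 and its analytic gradient in k.

    Uses  dw_t/dk_j = w_t (<d2_j>_w - d2[t,j]) / 2, whence
      d<c_i>_w/dk_j  = -Cov_w(c_i, d2_j)/2,
      dD_fwd/dk_j    =  (<d2_j>_{w0} - <d2_j>_w)/2,
      dD_rev/dk_j    =  Cov_w(d2_j, V)/2.
    """
    V = 0.5 * (d2 @ k)
    loga = logw0 - V
    m = loga.max()
    u = np.exp(loga - m)
    usum = u.sum()
    w = u / usum
    logZ = m + np.log(usum)  # log sum_t w0_t e^{-V_t}

    resid, active = _residuals(w, obs, noe_one_sided=noe_one_sided)
    M = obs.n_observables
    chi2_val = float(np.mean(resid**2))

    # Cov_w(c_i, d2_j) for all (i, j)
    means = obs.calc_matrix.T @ w
    d2_mean_w = d2.T @ w
    cov = (obs.calc_matrix * w[:, None]).T @ d2 - np.outer(means, d2_mean_w)
    rp = np.where(active, resid, 0.0) / obs.sigma
    grad_chi2 = (cov.T @ rp) / M

    Vbar_w0 = float(w0 @ V)
    if kl_direction == "forward":
        dkl = Vbar_w0 + logZ
        grad_kl = 0.5 * (d2.T @ w0 - d2_mean_w)
    else:
        Vbar_w = float(w @ V)
        dkl = -Vbar_w - logZ
        grad_kl = 0.5 * (d2.T @ (w * V) - d2_mean_w * Vbar_w)

    return theta * dkl + chi2_val, theta * grad_kl + grad_chi2


def cost(
    k: np.ndarray,
    theta: float,
    prior: Ensemble,
    obs: ObservableSet,
    d2: np.ndarray | None = None,
    kl_direction: KLDirection = "forward",
    *,
    noe_one_sided: bool = True,
) -> float:
    """Regularized cost  theta * D_KL + chi^2  evaluated at weights_from_k(k)."""
    if theta <= 0:
        raise ValueError("theta must be strictly positive")
    if d2 is None:
        d2 = deviation_matrix(obs, noe_one_sided=noe_one_sided)
    k = np.atleast_1d(np.asarray(k, dtype=float))
    w = weights_from_k(k, prior, d2)
    if kl_direction == "forward":
        dkl = kl_forward(prior, w)
    else:
        dkl = kl_reverse(w, prior)
    return theta * dkl + chi2(w, obs, noe_one_sided=noe_one_sided)


def optimize_k(
    theta: float,
    prior: Ensemble,
    obs: ObservableSet,
    *,
    kl_direction: KLDirection = "forward",
    noe_one_sided: bool = True,
    k0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 1000,
    nonnegative: bool = False,
) -> RefinementResult:
    """Minimize cost(k) = theta * D_KL + chi^2 over the k-vector.

    A quasi-Newton (L-BFGS-B) minimization with analytic gradients,
    initialized at k = 0 so the optimum can never be worse than the prior
    (cost(k_opt) <= cost(0) = chi^2_init).  Deterministic for fixed inputs.

    Parameters
    ----------
    theta
        Regularization strength; large theta keeps the ensemble close to
        the prior, small theta prioritizes agreement with experiment.
    kl_direction
        "forward" (mode-covering, default) or "reverse" (mode-seeking).
    noe_one_sided
        Treat NOE upper bounds as one-sided restraints (default True).
    k0
        Initial k (default zeros).
    tol
        Convergence tolerance on the relative cost change.
    max_iter
        Iteration budget; exceeded budget is reported via ``converged``.
    nonnegative
        Constrain k >= 0 (physical umbrella force constants).
    """
    from .selection import ensemble_preservation  # deferred: avoids cycle

    if theta <= 0:
        raise ValueError("theta must be strictly positive")
    if kl_direction not in ("forward", "reverse"):
        raise ValueError(f"unknown kl_direction {kl_direction!r}")
    _require_preconditioned(obs)
    if prior.n_conformers != obs.n_conformers:
        raise ValueError("prior and observable set disagree on N")

    d2 = deviation_matrix(obs, noe_one_sided=noe_one_sided)
    w0 = prior.weights
    with np.errstate(divide="ignore"):
        logw0 = np.where(w0 > 0, np.log(np.where(w0 > 0, w0, 1.0)), -np.inf)

    M = obs.n_observables
    kstart = np.zeros(M) if k0 is None else np.asarray(k0, dtype=float).copy()
    if kstart.size != M:
        raise ValueError("k0 length must match the number of observables")

    chi2_init = chi2(prior, obs, noe_one_sided=noe_one_sided)

    def fun(k: np.ndarray) -> tuple[float, np.ndarray]:
        return _cost_and_grad(
            k, theta, w0, logw0, d2, obs, kl_direction, noe_one_sided
        )

    if chi2_init == 0.0 and k0 is None:
        # perfect prior: no improvement possible, identity is the optimum
        k_opt = np.zeros(M)
        res_nit, res_success = 0, True
    else:
        bounds = [(0.0, None)] * M if nonnegative else None
        res = minimize(
            fun,
            kstart,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
        )
        k_opt = res.x
        res_nit, res_success = int(res.nit), bool(res.success)
        if not res_success:
            # a line search that stalls at machine precision is convergence:
            # accept the iterate if a small gradient step cannot improve it
            f0, g0 = fun(k_opt)
            gn = np.abs(g0).max()
            if gn == 0.0:
                res_success = True
            else:
                f1, _ = fun(k_opt - 1e-8 * g0 / gn)
                if f1 >= f0 - 1e-12 * max(1.0, abs(f0)):
                    res_success = True
        # never return an iterate worse than the k=0 identity
        if fun(k_opt)[0] > fun(np.zeros(M))[0]:
            k_opt = np.zeros(M)

    return _finalize(
        k_opt, theta, prior, obs, d2, kl_direction, noe_one_sided,
        chi2_init, res_success, res_nit,
    )


def _finalize(
    k_opt: np.ndarray,
    theta: float,
    prior: Ensemble,
    obs: ObservableSet,
    d2: np.ndarray,
    kl_direction: KLDirection,
    noe_one_sided: bool,
    chi2_init: float,
    converged: bool,
    n_iterations: int,
) -> RefinementResult:
    from .selection import ensemble_preservation  # deferred: avoids cycle

    w_opt = weights_from_k(k_opt, prior, d2)
    dkl_f = kl_forward(prior, w_opt)
    dkl_r = kl_reverse(w_opt, prior)
    chi2_opt = chi2(w_opt, obs, noe_one_sided=noe_one_sided)
    dkl_used = dkl_f if kl_direction == "forward" else dkl_r
    return RefinementResult(
        k_opt=k_opt,
        weights_opt=w_opt,
        chi2_init=chi2_init,
        chi2_opt=chi2_opt,
        dkl_forward=dkl_f,
        dkl_reverse=dkl_r,
        cost=theta * dkl_used + chi2_opt,
        ensemble_preservation=ensemble_preservation(w_opt, prior),
        theta=float(theta),
        converged=converged,
        n_iterations=n_iterations,
    )


def regularization_path(
    theta_grid: np.ndarray,
    prior: Ensemble,
    obs: ObservableSet,
    *,
    kl_direction: KLDirection = "forward",
    noe_one_sided: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
    nonnegative: bool = False,
) -> list[RefinementResult]:
    """Optimize k along a theta grid, robust to local minima.

    The cost is convex in k through the forward-KL term but not through
    chi^2, so at small theta independent optimizations can land in
    different local basins.  This routine collects candidate k-vectors
    from a cold start at every theta plus descending and ascending
    warm-start continuation sweeps, then assigns each theta the candidate
    with the lowest cost *over the shared pool*.  Selecting from a shared
    candidate set guarantees that D_KL is non-increasing and chi^2
    non-decreasing in theta (the exchange argument for argmins of
    theta*D + chi^2 over a common feasible set), while each solution is
    at least as good as the cold-start optimum.  Deterministic.

    Returns one :class:`RefinementResult` per grid point, ascending theta.
    """
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("theta grid must be strictly positive and ascending")
    d2 = deviation_matrix(obs, noe_one_sided=noe_one_sided)
    chi2_init = chi2(prior, obs, noe_one_sided=noe_one_sided)
    M = obs.n_observables

    def run(theta: float, k0: np.ndarray | None) -> RefinementResult:
        return optimize_k(
            theta, prior, obs, kl_direction=kl_direction,
            noe_one_sided=noe_one_sided, k0=k0, tol=tol,
            max_iter=max_iter, nonnegative=nonnegative,
        )

    # candidate pool: (k, converged, n_iterations)
    pool: list[tuple[np.ndarray, bool, int]] = [(np.zeros(M), True, 0)]
    cold = [run(t, None) for t in grid]
    pool += [(r.k_opt, r.converged, r.n_iterations) for r in cold]
    for order in (range(grid.size - 1, -1, -1), range(grid.size)):
        prev: np.ndarray | None = None
        for i in order:
            r = run(grid[i], prev) if prev is not None else cold[i]
            if prev is not None:
                pool.append((r.k_opt, r.converged, r.n_iterations))
            prev = r.k_opt

    results = []
    for theta in grid:
        costs = [
            cost(k, theta, prior, obs, d2, kl_direction,
                 noe_one_sided=noe_one_sided)
            for k, _, _ in pool
        ]
        k_best, conv, nit = pool[int(np.argmin(costs))]
        results.append(
            _finalize(k_best, theta, prior, obs, d2, kl_direction,
                      noe_one_sided, chi2_init, conv, nit)
        )
    return results
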