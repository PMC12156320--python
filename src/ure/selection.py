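"""Regularization-strength selection and overfitting diagnostics.

The hyper-parameter theta balances agreement with experiment against
divergence from the prior ensemble.  It is estimated by k-fold
cross-validation over *observables* (not conformers): for each theta and
fold, the k-vector is optimized on the training observables only and the
resulting weights are scored on the held-out observables with

    validation score = sigmoid(log(chi^2 / chi^2_init)),

which is 0.5 for no change, below 0.5 when the reweighting also improves
observables it never saw (genuine signal), and above 0.5 when held-out
agreement worsens (overfitting).  The ensemble-preservation diagnostic
complements the score: overfitting collapses weight onto a few conformers,
which preservation detects even when chi^2 looks good.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import KLDirection, chi2, kl_reverse, regularization_path
from .ensemble import Ensemble, ObservableSet

__all__ = [
    "FoldSplit",
    "ThetaScan",
    "validation_score",
    "make_folds",
    "cross_validate_theta",
    "ensemble_preservation",
    "select_theta",
    "default_theta_grid",
]

#: ratio floor guarding sigmoid(log x) against chi^2 = 0 on a fold
_RATIO_FLOOR = 1e-12


def validation_score(chi2_current: float, chi2_init: float) -> float:
    """sigmoid(ln(chi^2 / chi^2_init)) = ratio / (1 + ratio), in (0, 1).

    0.5 means the weights left agreement unchanged; < 0.5 improvement;
    > 0.5 worsening.  Scale-invariant in the pair (chi^2, chi^2_init).
    A vanishing chi^2 is floored at ratio 1e-12 to stay inside (0, 1).
    """
    if chi2_init <= 0:
        raise ValueError("chi2_init must be strictly positive")
    if chi2_current < 0:
        raise ValueError("chi2 cannot be negative")
    ratio = max(chi2_current / chi2_init, _RATIO_FLOOR)
    return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class FoldSplit:
    """One train/validation split over observable indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_idx, dtype=int)
        va = np.asarray(self.val_idx, dtype=int)
        if tr.size == 0 or va.size == 0:
            raise ValueError("both train and validation sets must be non-empty")
        if np.intersect1d(tr, va).size:
            raise ValueError("train and validation sets must be disjoint")
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "val_idx", va)


def make_folds(
    M: int,
    n_folds: int = 5,
    val_fraction: float | None = None,
    seed: int = 0,
) -> list[FoldSplit]:
    """Seeded train/validation splits over M observables.

    With ``val_fraction = 1/n_folds`` (the default) the validation sets
    form a disjoint partition, so every observable is held out exactly
    once.  Other fractions (e.g. 1/4 with five folds, the 75/25 split
    useful for very small observable sets) draw each fold's validation
    set independently without replacement.
    """
    if M < 2:
        raise ValueError("need at least 2 observables to cross-validate")
    if not 2 <= n_folds <= M:
        raise ValueError("need M >= n_folds >= 2")
    rng = np.random.default_rng(seed)
    everything = np.arange(M)
    if val_fraction is None or abs(val_fraction - 1.0 / n_folds) < 1e-12:
        perm = rng.permutation(M)
        chunks = np.array_split(perm, n_folds)
        return [
            FoldSplit(np.setdiff1d(everything, np.sort(c)), np.sort(c), seed)
            for c in chunks
        ]
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    n_val = max(1, round(M * val_fraction))
    if n_val >= M:
        raise ValueError("val_fraction leaves no training observables")
    folds = []
    for _ in range(n_folds):
        va = np.sort(rng.choice(M, size=n_val, replace=False))
        folds.append(FoldSplit(np.setdiff1d(everything, va), va, seed))
    return folds


def ensemble_preservation(
    weights: Ensemble | np.ndarray, prior: Ensemble | np.ndarray
) -> float:
    """Percent of the prior ensemble effectively retained after reweighting.

    Defined as 100 * exp(-D_KL(w || w0)) (reverse KL): the exponential of
    the negative relative entropy is the effective retained fraction of
    the prior.  100 iff the weights are unchanged; collapsing onto one of
    n equally weighted prior conformers gives 100/n; near 0 when a very
    low number of conformations carry all the weight.

    This definition is deliberately isolated here so it can be swapped
    without touching the rest of the package.
    """
    return 100.0 * float(np.exp(-kl_reverse(weights, prior)))


def default_theta_grid(n: int = 40) -> np.ndarray:
    """Log-spaced theta grid over [1e-3, 1e2], bracketing useful strengths."""
    return np.logspace(-3, 2, n)


@dataclass(frozen=True)
class ThetaScan:
    """Cross-validation scan over a theta grid.

    ``train_score``, ``val_score`` and ``ep`` have shape
    (n_theta, n_folds); scores lie strictly inside (0, 1), preservation
    in (0, 100].  ``theta_recommended`` is None when the scan found no
    interior minimum ("no recommendation").
    """

    theta_grid: np.ndarray
    train_score: np.ndarray
    val_score: np.ndarray
    ep: np.ndarray
    seed: int
    theta_recommended: float | None = None

    @property
    def mean_val_score(self) -> np.ndarray:
        return self.val_score.mean(axis=1)

    @property
    def sd_val_score(self) -> np.ndarray:
        return self.val_score.std(axis=1, ddof=1)

    @property
    def mean_train_score(self) -> np.ndarray:
        return self.train_score.mean(axis=1)

    @property
    def ep_curve(self) -> np.ndarray:
        """Mean ensemble preservation per theta, from training optimizations."""
        return self.ep.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (theta, fold)."""
        n_theta, n_folds = self.val_score.shape
        return pd.DataFrame(
            {
                "theta": np.repeat(self.theta_grid, n_folds),
                "fold": np.tile(np.arange(n_folds), n_theta),
                "train_score": self.train_score.ravel(),
                "val_score": self.val_score.ravel(),
                "ep": self.ep.ravel(),
            }
        )


def cross_validate_theta(
    prior: Ensemble,
    obs: ObservableSet,
    theta_grid: Sequence[float] | np.ndarray | None = None,
    n_folds: int = 5,
    val_fraction: float | None = None,
    seed: int = 0,
    *,
    kl_direction: KLDirection = "forward",
    noe_one_sided: bool = True,
    folds: list[FoldSplit] | None = None,
) -> ThetaScan:
    """Scan theta by k-fold cross-validation over observables.

    For each theta and fold, the k-vector is optimized on the training
    observables only; training and validation scores are
    sigmoid(log(chi^2/chi^2_init)) on the respective observable subsets,
    and the preservation curve comes from the training-data optimizations.
    Bit-reproducible for a fixed seed.
    """
    grid = (
        default_theta_grid()
        if theta_grid is None
        else np.asarray(theta_grid, dtype=float)
    )
    if grid.size == 0:
        raise ValueError("theta grid must be non-empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("theta grid must be strictly positive and ascending")
    if folds is None:
        folds = make_folds(obs.n_observables, n_folds, val_fraction, seed)
    for f in folds:
        if f.train_idx.size == 0:
            raise ValueError("fold with zero training observables")

    train_score = np.empty((grid.size, len(folds)))
    val_score = np.empty_like(train_score)
    ep = np.empty_like(train_score)
    for j, fold in enumerate(folds):
        obs_tr = obs.subset(fold.train_idx)
        obs_va = obs.subset(fold.val_idx)
        chi2_init_tr = chi2(prior, obs_tr, noe_one_sided=noe_one_sided)
        chi2_init_va = chi2(prior, obs_va, noe_one_sided=noe_one_sided)
        path = regularization_path(
            grid, prior, obs_tr,
            kl_direction=kl_direction, noe_one_sided=noe_one_sided,
        )
        for i, res in enumerate(path):
            w = res.weights_opt
            train_score[i, j] = validation_score(res.chi2_opt, chi2_init_tr)
            val_score[i, j] = validation_score(
                chi2(w, obs_va, noe_one_sided=noe_one_sided), chi2_init_va
            )
            ep[i, j] = res.ensemble_preservation

    scan = ThetaScan(grid, train_score, val_score, ep, seed)
    return ThetaScan(
        grid, train_score, val_score, ep, seed, select_theta(scan)
    )


def select_theta(scan: ThetaScan, rel_tol: float = 0.01) -> float | None:
    """Pick theta at the minimum of the mean validation-score curve.

    Returns None ("no recommendation") when the minimum sits on the upper
    grid boundary — a curve still decreasing at the largest theta wants no
    reweighting at all and gives nothing to recommend, mirroring scans
    that fail to find a minimum.  (A minimum at the *smallest* theta is a
    recommendation: the scan wants the strongest refinement on offer.)
    When several thetas score within ``rel_tol`` (relative) of the
    minimum, the largest — i.e. the most conservative, least-reweighting
    — theta is returned.
    """
    if scan.theta_grid.size == 0:
        raise ValueError("empty theta grid")
    mean = scan.mean_val_score
    i_min = int(np.argmin(mean))
    if i_min == mean.size - 1:
        return None
    qualifying = np.nonzero(mean <= mean[i_min] * (1.0 + rel_tol))[0]
    return float(scan.theta_grid[qualifying.max()])
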