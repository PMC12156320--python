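"""Weighted conformational ensembles and ensemble-averaging operators.

A conformational ensemble is a set of N conformers, each carrying a
statistical weight interpreted as its probability of occurrence.  Weights
are nonnegative and sum to one.  Experimental observables are population
averages, so comparing a simulated ensemble with experiment requires the
weighted ensemble average of the per-conformer back-calculated values —
a plain linear average for most observables, and an r^-3 / r^-6 power
average for NOE-derived interproton distances, whose signal intensity
falls off steeply with distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ObservableClass",
    "Ensemble",
    "ObservableSet",
    "InvalidWeightsError",
    "normalize_weights",
    "linear_average",
    "noe_average",
]

#: tolerance accepted on the input weight sum before exact renormalization
WEIGHT_SUM_TOL = 1e-9


class InvalidWeightsError(ValueError):
    """Raised when a weight vector cannot represent a probability distribution."""


class ObservableClass(str, Enum):
    """Experimental observable classes handled by the refinement."""

    SHIFT = "SHIFT"  # chemical shift, ppm
    JCOUPLING = "JCOUPLING"  # three-bond scalar coupling, Hz
    NOE_UPPER = "NOE_UPPER"  # NOE-derived upper distance bound, Angstrom


def normalize_weights(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize nonnegative raw weights to a probability vector.

    Parameters
    ----------
    raw
        Nonnegative, finite values with at least one strictly positive entry.

    Returns
    -------
    numpy.ndarray
        Weights proportional to ``raw`` summing to one (within 1e-12).

    Raises
    ------
    InvalidWeightsError
        If any entry is negative or non-finite, or all entries are zero.
    """
    w = np.asarray(raw, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise InvalidWeightsError("weights must be a non-empty 1-D array")
    if not np.all(np.isfinite(w)):
        raise InvalidWeightsError("weights must be finite")
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise InvalidWeightsError("at least one weight must be positive")
    return w / total


@dataclass(frozen=True)
class Ensemble:
    """A weighted conformational ensemble.

    Attributes
    ----------
    weights
        Probability per conformer; nonnegative, summing to one.  Input may
        deviate from unit sum by at most ``WEIGHT_SUM_TOL`` (1e-9) and is
        renormalized exactly on construction — downstream exponentials
        amplify drift otherwise.  Zero weights are permitted (sparse priors).
    conformer_ids
        Opaque labels, one per conformer.  Defaults to ``"c0000" ...``.
    """

    weights: np.ndarray
    conformer_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise InvalidWeightsError("ensemble needs at least one conformer")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise InvalidWeightsError("weights must be finite and nonnegative")
        total = w.sum()
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise InvalidWeightsError(
                f"weights sum to {total!r}, outside 1 ± {WEIGHT_SUM_TOL}"
            )
        w = w / total
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        ids = tuple(self.conformer_ids) or tuple(
            f"c{i:04d}" for i in range(w.size)
        )
        if len(ids) != w.size:
            raise ValueError("conformer_ids length must match weights")
        object.__setattr__(self, "conformer_ids", ids)

    @classmethod
    def from_raw(
        cls, raw: Sequence[float], conformer_ids: Sequence[str] = ()
    ) -> "Ensemble":
        """Build an ensemble from unnormalized nonnegative weights."""
        return cls(normalize_weights(raw), tuple(conformer_ids))

    @classmethod
    def uniform(cls, n: int, conformer_ids: Sequence[str] = ()) -> "Ensemble":
        """Uniform ensemble over ``n`` conformers (the unbiased-MD prior)."""
        return cls(np.full(n, 1.0 / n), tuple(conformer_ids))

    @property
    def n_conformers(self) -> int:
        return self.weights.size

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class ObservableSet:
    """Experimental observables paired with per-conformer back-calculations.

    Attributes
    ----------
    labels
        Unique text label per observable (length M).
    obs_class
        :class:`ObservableClass` per observable.
    exp_value
        Experimental value per observable (ppm, Hz, or Angstrom for NOE
        upper bounds before preconditioning).
    sigma
        Strictly positive total uncertainty per observable, same units as
        the value.  This is the combined experimental + back-calculation
        error; no further combination happens downstream.
    calc_matrix
        Back-calculated value of observable i for conformer t, shape (N, M).
    noe_preconditioned
        True once NOE distances have been linearized to r^-6 space (see
        :func:`ure.io.precondition_noe`).  The refinement requires NOE
        observables to be preconditioned.
    """

    labels: tuple[str, ...]
    obs_class: tuple[ObservableClass, ...]
    exp_value: np.ndarray
    sigma: np.ndarray
    calc_matrix: np.ndarray
    noe_preconditioned: bool = False

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        classes = tuple(ObservableClass(c) for c in self.obs_class)
        exp = np.atleast_1d(np.asarray(self.exp_value, dtype=float))
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        calc = np.atleast_2d(np.asarray(self.calc_matrix, dtype=float))
        m = len(labels)
        if m == 0:
            raise ValueError("observable set must contain at least one observable")
        if len(set(labels)) != m:
            raise ValueError("observable labels must be unique")
        if len(classes) != m or exp.size != m or sig.size != m:
            raise ValueError("labels, obs_class, exp_value, sigma must share length M")
        if calc.shape[1] != m:
            raise ValueError(
                f"calc_matrix has {calc.shape[1]} columns, expected M={m}"
            )
        if not (np.all(np.isfinite(exp)) and np.all(np.isfinite(sig))
                and np.all(np.isfinite(calc))):
            raise ValueError("observable values must be finite")
        if np.any(sig <= 0):
            raise ValueError("sigma must be strictly positive")
        noe = np.array([c is ObservableClass.NOE_UPPER for c in classes])
        if noe.any() and not self.noe_preconditioned:
            if np.any(exp[noe] <= 0) or np.any(calc[:, noe] <= 0):
                raise ValueError("NOE distances and bounds must be strictly positive")
        exp.setflags(write=False)
        sig.setflags(write=False)
        calc.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "obs_class", classes)
        object.__setattr__(self, "exp_value", exp)
        object.__setattr__(self, "sigma", sig)
        object.__setattr__(self, "calc_matrix", calc)

    @property
    def n_conformers(self) -> int:
        return self.calc_matrix.shape[0]

    @property
    def n_observables(self) -> int:
        return len(self.labels)

    @property
    def noe_mask(self) -> np.ndarray:
        """Boolean mask over observables selecting NOE upper bounds."""
        return np.array(
            [c is ObservableClass.NOE_UPPER for c in self.obs_class]
        )

    def subset(self, indices: Sequence[int] | np.ndarray) -> "ObservableSet":
        """Restrict to the observables at ``indices`` (used by CV folds)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("cannot build an empty observable subset")
        return ObservableSet(
            labels=tuple(self.labels[i] for i in idx),
            obs_class=tuple(self.obs_class[i] for i in idx),
            exp_value=self.exp_value[idx],
            sigma=self.sigma[idx],
            calc_matrix=self.calc_matrix[:, idx],
            noe_preconditioned=self.noe_preconditioned,
        )

    def replace_exp(self, exp_value: np.ndarray) -> "ObservableSet":
        """Return a copy with new experimental values (synthetic fixtures)."""
        return ObservableSet(
            labels=self.labels,
            obs_class=self.obs_class,
            exp_value=np.asarray(exp_value, dtype=float),
            sigma=self.sigma,
            calc_matrix=self.calc_matrix,
            noe_preconditioned=self.noe_preconditioned,
        )

    def warn_if_degenerate(self) -> None:
        """Warn about zero-variance observable columns.

        A column constant across conformers adds a constant to the bias
        potential that cancels in the normalization; it still counts in
        chi-squared but cannot steer the reweighting.
        """
        spread = self.calc_matrix.max(axis=0) - self.calc_matrix.min(axis=0)
        for j in np.nonzero(spread == 0)[0]:
            warnings.warn(
                f"observable {self.labels[j]!r} is constant across conformers; "
                "it cannot influence the reweighting",
                stacklevel=2,
            )


def _check_lengths(weights: np.ndarray, values: np.ndarray) -> None:
    if weights.shape != values.shape:
        raise ValueError(
            f"weights (len {weights.size}) and values (len {values.size}) "
            "must have the same length"
        )


def linear_average(
    weights: np.ndarray | Ensemble, values: Sequence[float] | np.ndarray
) -> float:
    """Weighted ensemble average  <O> = sum_t w_t * O_t.

    ``weights`` must be normalized (or an :class:`Ensemble`); the result
    lies within [min(values), max(values)].
    """
    w = weights.weights if isinstance(weights, Ensemble) else np.asarray(weights, float)
    v = np.asarray(values, dtype=float)
    _check_lengths(w, v)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return float(w @ v)


def noe_average(
    weights: np.ndarray | Ensemble,
    distances: Sequence[float] | np.ndarray,
    exponent: int = 6,
) -> float:
    """Power-averaged effective NOE distance  (sum_t w_t r_t^-p)^(-1/p).

    NOE signal intensity decays as r^-6 (r^-3 for fast internal motion), so
    close conformers dominate: the result is always <= the linear average
    and >= the minimum distance.

    Parameters
    ----------
    weights
        Normalized weights or an :class:`Ensemble`.
    distances
        Strictly positive interproton distances in Angstrom, one per conformer.
    exponent
        3 or 6.
    """
    w = weights.weights if isinstance(weights, Ensemble) else np.asarray(weights, float)
    r = np.asarray(distances, dtype=float)
    _check_lengths(w, r)
    if exponent not in (3, 6):
        raise ValueError("exponent must be 3 or 6")
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("distances must be strictly positive and finite")
    return float((w @ r ** (-float(exponent))) ** (-1.0 / exponent))
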