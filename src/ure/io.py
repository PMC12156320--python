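"""Readers and writers for the two-file input convention.

Refinement needs two plain-text, whitespace-delimited files:

* an **experimental** file — one row per observable (label, value, total
  uncertainty sigma), organized in blocks introduced by a ``# DATA=CLASS``
  header (``SHIFT``, ``JCOUPLING`` or ``NOE_UPPER``); other ``#`` lines
  are comments;
* a **calculated** file — one row per conformer, first column the
  conformer id, remaining columns the back-calculated observables, with
  a header row naming the columns after the experimental labels (any
  column order).

sigma is the *total* uncertainty (experiment + back-calculation combined
upstream); the reader performs no error combination.  NOE-derived
distances are compared to upper bounds after linearization to r^-6 space
(:func:`precondition_noe`), which lets them be handled by linear
averaging inside the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import RefinementResult
from .ensemble import Ensemble, ObservableClass, ObservableSet

__all__ = [
    "ParseError",
    "ExperimentalRecord",
    "CalcTable",
    "read_experimental",
    "read_calculated",
    "to_observable_set",
    "load_observables",
    "precondition_noe",
    "write_weights",
    "read_weights",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


@dataclass(frozen=True)
class ExperimentalRecord:
    """One experimental observable: label, class, value and uncertainty."""

    label: str
    obs_class: ObservableClass
    value: float
    sigma: float


@dataclass(frozen=True)
class CalcTable:
    """Back-calculated observables, one row per conformer.

    ``matrix`` columns are aligned to the experimental records' label
    order regardless of the on-disk column order.
    """

    conformer_ids: tuple[str, ...]
    labels: tuple[str, ...]
    matrix: np.ndarray


def read_experimental(path: str | Path) -> list[ExperimentalRecord]:
    """Parse the experimental-data file into validated records, in file order."""
    records: list[ExperimentalRecord] = []
    seen: set[str] = set()
    current: ObservableClass | None = None
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.upper().startswith("DATA="):
                name = body.split("=", 1)[1].strip().upper()
                try:
                    current = ObservableClass(name)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unknown observable class {name!r}"
                    ) from None
            continue
        if current is None:
            raise ParseError(
                f"{path}:{lineno}: data before any '# DATA=<CLASS>' header"
            )
        tokens = line.split()
        if len(tokens) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 columns (label value sigma), "
                f"got {len(tokens)}"
            )
        label = tokens[0]
        if label in seen:
            raise ParseError(f"{path}:{lineno}: duplicated label {label!r}")
        try:
            value, sigma = float(tokens[1]), float(tokens[2])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric value or sigma"
            ) from None
        if not np.isfinite(value) or not np.isfinite(sigma):
            raise ParseError(f"{path}:{lineno}: value and sigma must be finite")
        if sigma <= 0:
            raise ParseError(f"{path}:{lineno}: sigma must be > 0, got {sigma}")
        if current is ObservableClass.NOE_UPPER and value <= 0:
            raise ParseError(
                f"{path}:{lineno}: NOE upper bound must be > 0, got {value}"
            )
        seen.add(label)
        records.append(ExperimentalRecord(label, current, value, sigma))
    if not records:
        raise ParseError(f"{path}: no observables found")
    return records


def read_calculated(
    path: str | Path, records: Sequence[ExperimentalRecord]
) -> CalcTable:
    """Parse the calculated-observables file, aligned to the records' labels."""
    try:
        frame = pd.read_csv(path, sep=r"\s+", comment="#", header=0)
    except pd.errors.ParserError as err:
        raise ParseError(f"{path}: {err}") from None
    if frame.shape[0] == 0:
        raise ParseError(f"{path}: no conformer rows found")
    ids = tuple(str(v) for v in frame.iloc[:, 0])
    have = list(frame.columns[1:])
    want = [r.label for r in records]
    missing = sorted(set(want) - set(have))
    extra = sorted(set(have) - set(want))
    if missing or extra:
        raise ParseError(
            f"{path}: column labels do not match experimental labels "
            f"(missing {missing}, unexpected {extra})"
        )
    sub = frame[want]
    if sub.isna().any().any():
        raise ParseError(f"{path}: missing or non-numeric cells")
    matrix = sub.to_numpy(dtype=float)
    return CalcTable(ids, tuple(want), matrix)


def to_observable_set(
    records: Sequence[ExperimentalRecord], table: CalcTable
) -> ObservableSet:
    """Assemble records and the aligned calculated table into an ObservableSet."""
    if tuple(r.label for r in records) != table.labels:
        raise ValueError("records and table are not aligned")
    return ObservableSet(
        labels=table.labels,
        obs_class=tuple(r.obs_class for r in records),
        exp_value=np.array([r.value for r in records]),
        sigma=np.array([r.sigma for r in records]),
        calc_matrix=table.matrix,
    )


def load_observables(
    exp_path: str | Path, calc_path: str | Path, *, precondition: bool = True
) -> tuple[ObservableSet, tuple[str, ...]]:
    """Read both input files; returns the (preconditioned) set and conformer ids."""
    records = read_experimental(exp_path)
    table = read_calculated(calc_path, records)
    obs = to_observable_set(records, table)
    if precondition:
        obs = precondition_noe(obs)
    return obs, table.conformer_ids


def precondition_noe(obs: ObservableSet) -> ObservableSet:
    """Linearize NOE distances to r^-6 space.

    Calculated distances r map to r^-6 and the experimental upper bound b
    to b^-6, so the steeply distance-weighted NOE average becomes a plain
    linear average during optimization.  The uncertainty follows by
    first-order propagation: sigma' = 6 b^-7 sigma.  Non-NOE observables
    are untouched.  The transform is recorded on the returned set (so
    reports can convert back to Angstrom) and applying it twice is an
    error.
    """
    if obs.noe_preconditioned:
        raise ValueError("NOE observables are already preconditioned")
    noe = obs.noe_mask
    if not noe.any():
        return ObservableSet(
            obs.labels, obs.obs_class, obs.exp_value, obs.sigma,
            obs.calc_matrix, noe_preconditioned=True,
        )
    if np.any(obs.exp_value[noe] <= 0) or np.any(obs.calc_matrix[:, noe] <= 0):
        raise ValueError("NOE distances and bounds must be strictly positive")
    exp = obs.exp_value.copy()
    sig = obs.sigma.copy()
    calc = obs.calc_matrix.copy()
    b = exp[noe]
    sig[noe] = 6.0 * b ** (-7.0) * sig[noe]
    exp[noe] = b ** (-6.0)
    calc[:, noe] = calc[:, noe] ** (-6.0)
    return ObservableSet(
        obs.labels, obs.obs_class, exp, sig, calc, noe_preconditioned=True
    )


def write_weights(
    path: str | Path,
    ensemble: Ensemble,
    result: RefinementResult | None = None,
    labels: Sequence[str] | None = None,
    extra_header: Sequence[str] = (),
) -> None:
    """Write a two-column (conformer_id, weight) table with a diagnostic header."""
    lines = ["# URE ensemble weights"]
    lines.extend(f"# {h}" for h in extra_header)
    if result is not None:
        lines += [
            f"# theta = {result.theta:.6g}",
            f"# chi2_init = {result.chi2_init:.12g}",
            f"# chi2_opt = {result.chi2_opt:.12g}",
            f"# dkl_forward = {result.dkl_forward:.12g}",
            f"# dkl_reverse = {result.dkl_reverse:.12g}",
            f"# ensemble_preservation = {result.ensemble_preservation:.6g}",
            f"# converged = {result.converged}",
        ]
        names = labels or [f"obs{i}" for i in range(result.k_opt.size)]
        for name, kv in zip(names, result.k_opt):
            lines.append(f"# k[{name}] = {kv:.12g}")
    for cid, w in zip(ensemble.conformer_ids, ensemble.weights):
        lines.append(f"{cid} {w:.16e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_weights(path: str | Path) -> Ensemble:
    """Read a two-column (conformer_id, weight) table back into an Ensemble."""
    ids: list[str] = []
    weights: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 columns (id weight)"
            )
        ids.append(tokens[0])
        try:
            weights.append(float(tokens[1]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric weight") from None
    if not weights:
        raise ParseError(f"{path}: no weights found")
    return Ensemble(np.asarray(weights), tuple(ids))
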