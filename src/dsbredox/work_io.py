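"""Work tables and dH/dlambda series: parsing, writing, and integration.

A non-equilibrium switching trajectory produces the derivative of the
Hamiltonian with respect to the coupling parameter lambda along the switch;
the work performed on the system is the lambda-integral of that derivative.
This module reads xvg-style two-column dH/dlambda files, integrates them to
scalar works, and round-trips CSV work tables.

Conventions
-----------
* forward = oxidized (lambda=0) -> reduced (lambda=1).
* A backward replica is recorded on its own 1 -> 0 path and its work is the
  work done *on that path* (positive-dissipation convention).  Negation into
  the forward frame happens inside the estimators, never here.
* Energies are kJ/mol throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Direction = Literal["forward", "backward"]

_DIRECTIONS = ("forward", "backward")


class WorkIOError(ValueError):
    """Raised for malformed work tables or dH/dlambda files."""


@dataclass(frozen=True)
class DhdlSeries:
    """Ordered (lambda, dH/dlambda) samples for one switching replica.

    lambda is dimensionless in [0, 1]; dH/dlambda is in kJ/mol (per unit
    lambda).  Forward series run lambda strictly increasing, backward series
    strictly decreasing.
    """

    replica_id: str
    direction: Direction
    lambdas: np.ndarray
    dhdl: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        dh = np.asarray(self.dhdl, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "dhdl", dh)
        if self.direction not in _DIRECTIONS:
            raise WorkIOError(f"unknown direction {self.direction!r}")
        if lam.ndim != 1 or dh.shape != lam.shape:
            raise WorkIOError("lambdas and dhdl must be 1-D arrays of equal length")
        if lam.size < 2:
            raise WorkIOError(f"need at least 2 points, got {lam.size}")
        if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(dh))):
            raise WorkIOError("non-finite values in dH/dlambda series")
        if lam.min() < 0.0 or lam.max() > 1.0:
            raise WorkIOError("lambda values must lie in [0, 1]")
        steps = np.diff(lam)
        if self.direction == "forward":
            if not np.all(steps > 0):
                raise WorkIOError("forward series requires strictly increasing lambda")
        else:
            if not np.all(steps < 0):
                raise WorkIOError("backward series requires strictly decreasing lambda")

    @property
    def n_points(self) -> int:
        return int(self.lambdas.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DhdlSeries):
            return NotImplemented
        return (
            self.replica_id == other.replica_id
            and self.direction == other.direction
            and np.array_equal(self.lambdas, other.lambdas)
            and np.array_equal(self.dhdl, other.dhdl)
        )


@dataclass(frozen=True)
class WorkSet:
    """Labeled collection of scalar works for one transition direction.

    Works are kJ/mol in the direction's own frame (see module docstring).
    NaN / infinite values are rejected; tied values are legitimate (bootstrap
    resamples and degenerate test sets contain them).
    """

    label: str
    direction: Direction
    works: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        w = np.asarray(self.works, dtype=float)
        object.__setattr__(self, "works", w)
        if self.direction not in _DIRECTIONS:
            raise WorkIOError(f"unknown direction {self.direction!r}")
        if w.ndim != 1 or w.size == 0:
            raise WorkIOError("works must be a non-empty 1-D array")
        if not np.all(np.isfinite(w)):
            raise WorkIOError("non-finite work values rejected")
        if self.temperature <= 0:
            raise WorkIOError(f"temperature must be positive, got {self.temperature}")

    @property
    def n(self) -> int:
        return int(self.works.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WorkSet):
            return NotImplemented
        return (
            self.label == other.label
            and self.direction == other.direction
            and self.temperature == other.temperature
            and np.array_equal(self.works, other.works)
        )


def read_dhdl(
    path: str | Path,
    direction: Direction,
    replica_id: str | None = None,
    time_range: tuple[float, float] | None = None,
) -> DhdlSeries:
    """Read an xvg-style two-column dH/dlambda file.

    Lines starting with ``#`` or ``@`` are comments/metadata.  Data lines
    hold at least two whitespace-separated numbers: (lambda-or-time,
    dH/dlambda).  By default the first column is already lambda; pass
    ``time_range=(t_start, t_end)`` when it is a time axis, and it is mapped
    linearly onto lambda in [0, 1] (reversed for backward series, whose
    lambda runs 1 -> 0 as time advances).
    """
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise WorkIOError(f"{path}: line {lineno}: expected >=2 columns")
            try:
                x, y = float(tokens[0]), float(tokens[1])
            except ValueError as exc:
                raise WorkIOError(
                    f"{path}: line {lineno}: non-numeric token in data row"
                ) from exc
            xs.append(x)
            ys.append(y)
    if len(xs) < 2:
        raise WorkIOError(f"{path}: need at least 2 data points, found {len(xs)}")
    lam = np.asarray(xs, dtype=float)
    if time_range is not None:
        t0, t1 = time_range
        if t1 <= t0:
            raise WorkIOError("time_range must satisfy t_end > t_start")
        frac = (lam - t0) / (t1 - t0)
        lam = frac if direction == "forward" else 1.0 - frac
    return DhdlSeries(
        replica_id=replica_id if replica_id is not None else path.stem,
        direction=direction,
        lambdas=lam,
        dhdl=np.asarray(ys, dtype=float),
    )


def integrate_work(series: DhdlSeries) -> float:
    """Trapezoidal work along the series' own switching path, kJ/mol.

    Integration follows the file order, so a backward series (lambda
    decreasing) naturally yields the work done on the 1 -> 0 path; no
    further sign adjustment is applied here.
    """
    if np.unique(series.lambdas).size != series.lambdas.size:
        raise WorkIOError("duplicate lambda values in series")
    return float(np.trapezoid(series.dhdl, series.lambdas))


def write_worksets(worksets: Iterable[WorkSet], path: str | Path) -> None:
    """Write work sets to CSV (`label,direction,work_kJ_mol,temperature_K`).

    Values are written via Python's shortest round-trip float repr, so a
    subsequent :func:`read_worksets` reproduces them bit-for-bit.
    """
    rows = []
    for ws in worksets:
        for w in ws.works:
            rows.append(
                {
                    "label": ws.label,
                    "direction": ws.direction,
                    "work_kJ_mol": repr(float(w)),
                    "temperature_K": repr(float(ws.temperature)),
                }
            )
    if not rows:
        raise WorkIOError("refusing to write an empty work table")
    pd.DataFrame(rows).to_csv(path, index=False)


def read_worksets(path: str | Path) -> list[WorkSet]:
    """Read a CSV work table into one WorkSet per (label, direction) group.

    Required columns: label, direction, work_kJ_mol; optional temperature_K
    (default 300 K).  Group order follows first appearance in the file.
    """
    df = pd.read_csv(
        path, dtype={"label": str, "direction": str}, float_precision="round_trip"
    )
    required = {"label", "direction", "work_kJ_mol"}
    missing = required - set(df.columns)
    if missing:
        raise WorkIOError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise WorkIOError(f"{path}: empty data section")
    bad = set(df["direction"]) - set(_DIRECTIONS)
    if bad:
        raise WorkIOError(f"{path}: unknown direction token(s) {sorted(bad)}")
    if "temperature_K" not in df.columns:
        df["temperature_K"] = 300.0
    out: list[WorkSet] = []
    for (label, direction), grp in df.groupby(["label", "direction"], sort=False):
        temps = grp["temperature_K"].astype(float).unique()
        if temps.size > 1:
            raise WorkIOError(
                f"{path}: inconsistent temperatures for ({label}, {direction})"
            )
        out.append(
            WorkSet(
                label=str(label),
                direction=direction,  # type: ignore[arg-type]
                works=grp["work_kJ_mol"].astype(float).to_numpy(),
                temperature=float(temps[0]),
            )
        )
    return out


def read_workset(path: str | Path) -> WorkSet:
    """Read a CSV expected to contain exactly one (label, direction) group."""
    sets = read_worksets(path)
    if len(sets) != 1:
        raise WorkIOError(
            f"{path}: expected exactly one (label, direction) group, found {len(sets)}"
        )
    return sets[0]


def paired_worksets(worksets: Sequence[WorkSet]) -> dict[str, tuple[WorkSet, WorkSet]]:
    """Group work sets into (forward, backward) pairs keyed by label."""
    by_label: dict[str, dict[str, WorkSet]] = {}
    for ws in worksets:
        slot = by_label.setdefault(ws.label, {})
        if ws.direction in slot:
            raise WorkIOError(f"duplicate ({ws.label}, {ws.direction}) work set")
        slot[ws.direction] = ws
    pairs: dict[str, tuple[WorkSet, WorkSet]] = {}
    for label, slot in by_label.items():
        if set(slot) != set(_DIRECTIONS):
            raise WorkIOError(f"label {label!r} lacks a forward/backward pair")
        pairs[label] = (slot["forward"], slot["backward"])
    return pairs
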