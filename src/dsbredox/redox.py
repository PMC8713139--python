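"""Reduction potentials and functional/structural classification.

The reduction free energy dG of a disulfide -> dithiol transformation maps
to a standard reduction potential through the Nernst relation for the
two-electron reduction,

    E_cal (V) = -dG / (n F),      n = 2,  F = 96.485 kJ mol^-1 V^-1,

reported here in mV.  Computed potentials are then put on the experimental
scale by a linear calibration E_corr = slope * E_cal + intercept, and a bond
is called *functional* (catalytic or allosteric) when its corrected
potential lies inside the literature window [-330, -89] mV, *structural*
otherwise.  Literature structural bonds sit below about -470 mV; a
structural call in the (-470, -330) mV gap is flagged as gray-zone but not
given a third class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import FARADAY_KJ_MOL_V
from .estimators import EstimatorName, bootstrap_se, get_estimator
from .work_io import WorkSet

Role = Literal["functional", "structural"]


class RedoxInputError(ValueError):
    """Raised for malformed classification inputs."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from computed to experimental-scale potential (mV)."""

    slope: float = 1.5
    intercept: float = -43.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise RedoxInputError("calibration slope must be nonzero")


@dataclass(frozen=True)
class ClassificationPolicy:
    """Potential windows (mV) for the functional/structural split.

    Boundaries are inclusive to the functional window.  ``structural_cut``
    only delimits the gray zone between the functional window and the
    literature structural regime; it does not create a third class.
    """

    functional_low: float = -330.0
    functional_high: float = -89.0
    structural_cut: float = -470.0

    def __post_init__(self) -> None:
        if not self.functional_low < self.functional_high:
            raise RedoxInputError("functional_low must be < functional_high")
        if not self.structural_cut < self.functional_low:
            raise RedoxInputError("structural_cut must be < functional_low")


@dataclass(frozen=True)
class RedoxRecord:
    """One disulfide bond's free energy, potentials, and assigned role."""

    bond_id: str
    domain: str
    dG: float
    e_cal: float
    e_corr: float
    role: Role
    gray_zone: bool = False
    se: float | None = None
    method: str | None = None


@dataclass(frozen=True)
class ReportSummary:
    """Per-role counts and corrected-potential extremes of a report."""

    n_functional: int
    n_structural: int
    extremes: dict  # role -> (most_negative_e_corr, least_negative_e_corr)


def nernst_potential(dG: float, n_electrons: int = 2) -> float:
    """Reduction potential in mV from a reduction free energy in kJ/mol."""
    if n_electrons < 1:
        raise RedoxInputError("n_electrons must be >= 1")
    return -dG / (n_electrons * FARADAY_KJ_MOL_V) * 1000.0


def calibrate(e_cal: float, model: CalibrationModel = CalibrationModel()) -> float:
    """Corrected potential E_corr = slope * E_cal + intercept (mV)."""
    return model.slope * e_cal + model.intercept


def classify(
    e_corr: float, policy: ClassificationPolicy = ClassificationPolicy()
) -> Role:
    """Functional iff functional_low <= E_corr <= functional_high, else structural."""
    if policy.functional_low <= e_corr <= policy.functional_high:
        return "functional"
    return "structural"


def is_gray_zone(
    e_corr: float, policy: ClassificationPolicy = ClassificationPolicy()
) -> bool:
    """True for structural calls between the window and the literature cut."""
    return policy.structural_cut < e_corr < policy.functional_low


BondInput = tuple  # (bond_id, domain, dG) or (bond_id, domain, WorkSet, WorkSet)


def build_report(
    bonds: Sequence[BondInput],
    model: CalibrationModel = CalibrationModel(),
    policy: ClassificationPolicy = ClassificationPolicy(),
    estimator: EstimatorName = "bar",
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[list[RedoxRecord], ReportSummary]:
    """Classify a panel of bonds given either dG values or work-set pairs.

    Each bond is ``(bond_id, domain, dG)`` or ``(bond_id, domain,
    forward_workset, backward_workset)``; in the latter case dG is estimated
    with the chosen estimator, plus a bootstrap SE when ``n_boot > 0``.
    Returns one record per bond and a summary with per-role counts and the
    extreme corrected potentials within each role.
    """
    ids = [b[0] for b in bonds]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise RedoxInputError(f"duplicate bond_id(s): {sorted(dupes)}")
    records: list[RedoxRecord] = []
    for bond in bonds:
        if len(bond) == 3:
            bond_id, domain, dg = bond
            se: float | None = None
            method = None
        elif len(bond) == 4:
            bond_id, domain, fwd, bwd = bond
            if not (isinstance(fwd, WorkSet) and isinstance(bwd, WorkSet)):
                raise RedoxInputError(f"bond {bond_id!r}: expected two WorkSets")
            est = get_estimator(estimator)(fwd, bwd)
            dg, method = est.dG, est.method
            se = (
                bootstrap_se(fwd, bwd, estimator=estimator, n_boot=n_boot, seed=seed)
                if n_boot > 0
                else None
            )
        else:
            raise RedoxInputError(f"bond entry of length {len(bond)} not understood")
        e_cal = nernst_potential(float(dg))
        e_corr = calibrate(e_cal, model)
        role = classify(e_corr, policy)
        records.append(
            RedoxRecord(
                bond_id=str(bond_id), domain=str(domain), dG=float(dg),
                e_cal=e_cal, e_corr=e_corr, role=role,
                gray_zone=(role == "structural" and is_gray_zone(e_corr, policy)),
                se=se, method=method,
            )
        )
    return records, summarize(records)


def summarize(records: Iterable[RedoxRecord]) -> ReportSummary:
    """Per-role counts and corrected-potential extremes (order-invariant)."""
    by_role: dict[str, list[float]] = {"functional": [], "structural": []}
    for r in records:
        by_role[r.role].append(r.e_corr)
    extremes = {
        role: (min(vals), max(vals)) for role, vals in by_role.items() if vals
    }
    return ReportSummary(
        n_functional=len(by_role["functional"]),
        n_structural=len(by_role["structural"]),
        extremes=extremes,
    )


def classify_potentials(
    e_corr_values: Sequence[float],
    policy: ClassificationPolicy = ClassificationPolicy(),
) -> list[Role]:
    """Vector convenience: classify already-corrected potentials (mV)."""
    return [classify(float(e), policy) for e in e_corr_values]


def correlate_distance_potential(
    pairs: Sequence[tuple[float, float]]
) -> float:
    """Spearman rank correlation between bond-site distance and potential.

    Ties are handled by mid-ranks (scipy convention).  Requires >= 3 pairs.
    """
    if len(pairs) < 3:
        raise RedoxInputError(f"need >= 3 (distance, potential) pairs, got {len(pairs)}")
    d, e = zip(*pairs)
    return float(stats.spearmanr(d, e).statistic)


def records_to_frame(records: Iterable[RedoxRecord]) -> pd.DataFrame:
    """Tabulate records with the published table's column order."""
    return pd.DataFrame(
        [
            {
                "domain": r.domain,
                "bond_id": r.bond_id,
                "dG_kJ_mol": r.dG,
                "se_kJ_mol": r.se,
                "E_cal_mV": r.e_cal,
                "E_corr_mV": r.e_corr,
                "role": r.role,
                "gray_zone": r.gray_zone,
                "method": r.method,
            }
            for r in records
        ]
    )


def format_report(records: Iterable[RedoxRecord]) -> str:
    """Human-readable fixed-width table of a classification report."""
    df = records_to_frame(records)
    lines = [f"{'Domain':<10}{'Bond':<18}{'dG':>8}{'E_cal':>10}{'E_corr':>10}  Role"]
    for _, r in df.iterrows():
        lines.append(
            f"{r.domain:<10}{r.bond_id:<18}{r.dG_kJ_mol:>8.2f}"
            f"{r.E_cal_mV:>10.2f}{r.E_corr_mV:>10.2f}  {r.role}"
            + ("  (gray zone)" if r.gray_zone else "")
        )
    return "\n".join(lines)
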