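"""Synthetic inputs with the statistical structure the analysis assumes.

The Crooks fluctuation theorem, P_F(W) / P_B(-W) = exp(beta (W - dG)),
admits exactly one Gaussian solution pair: equal variances sigma^2 and
means dG +/- beta sigma^2 / 2.  The generator draws forward and backward
work samples from that pair, so every estimator in the package can be
exercised at known truth — dissipation is parameterized by sigma through
the CFT constraint rather than independently.

Also provided: dH/dlambda series with a prescribed integral, multi-bond
panels mimicking the published study design (17 bonds, 500 switching
replicas per direction at 300 K), and deterministic toy structure/topology
fixtures.  None of this emulates MD time correlation or anharmonic work
tails; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, beta as beta_of_T
from .redox import (
    CalibrationModel,
    ClassificationPolicy,
    calibrate,
    classify,
    nernst_potential,
)
from .topology import ResidueTemplate, TemplateAtom
from .work_io import DhdlSeries, WorkSet


@dataclass(frozen=True)
class CftModel:
    """A Crooks-consistent Gaussian work-distribution pair at known truth."""

    dG_true: float
    sigma: float
    n_per_direction: int = 500
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.n_per_direction < 1:
            raise ValueError("n_per_direction must be >= 1")

    @property
    def beta(self) -> float:
        return beta_of_T(self.temperature)

    @property
    def mean_forward(self) -> float:
        """Forward-work mean dG + beta sigma^2 / 2 (kJ/mol)."""
        return self.dG_true + self.beta * self.sigma**2 / 2.0

    @property
    def mean_reverse(self) -> float:
        """Negated-backward-work mean dG - beta sigma^2 / 2 (kJ/mol)."""
        return self.dG_true - self.beta * self.sigma**2 / 2.0

    def log_density_ratio(self, w: np.ndarray | float) -> np.ndarray | float:
        """ln[p_F(W) / p_B~(W)] from the closed-form Gaussian densities.

        Analytically equal to beta (W - dG_true) for every W — the Crooks
        identity the generator is built to satisfy.
        """
        w = np.asarray(w, dtype=float)
        mu_f, mu_r, s2 = self.mean_forward, self.mean_reverse, self.sigma**2
        out = (-((w - mu_f) ** 2) + (w - mu_r) ** 2) / (2.0 * s2)
        return float(out) if out.ndim == 0 else out


def sample_cft_works(model: CftModel, label: str = "bond") -> tuple[WorkSet, WorkSet]:
    """Draw a (forward, backward) work-set pair from a CFT-consistent model.

    Backward works are stored in the backward frame (work done on the
    1 -> 0 path): the negated draws from N(dG - beta sigma^2/2, sigma^2).
    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_per_direction
    fwd = rng.normal(model.mean_forward, model.sigma, size=n)
    rev = rng.normal(model.mean_reverse, model.sigma, size=n)
    return (
        WorkSet(label, "forward", fwd, model.temperature),
        WorkSet(label, "backward", -rev, model.temperature),
    )


def synth_dhdl(
    target_work: float,
    n_points: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    direction: str = "forward",
    replica_id: str = "synthetic",
) -> DhdlSeries:
    """A dH/dlambda series whose trapezoidal integral is ``target_work``.

    A smooth base curve (a cosine hump emulating the characteristic rise
    and fall of the switching-derivative profile) plus seeded Gaussian
    noise is shifted by a constant so the integral along the series' own
    path equals the target exactly.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    rng = np.random.default_rng(seed)
    lam = np.linspace(0.0, 1.0, n_points)
    if direction == "backward":
        lam = lam[::-1]
    curve = 5.0 * np.cos(2.0 * np.pi * lam)
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd, size=n_points)
    integral = np.trapezoid(curve, lam)
    span = lam[-1] - lam[0]
    curve = curve + (target_work - integral) / span
    return DhdlSeries(replica_id=replica_id, direction=direction,  # type: ignore[arg-type]
                      lambdas=lam, dhdl=curve)


def make_bond_panel(
    n_bonds: int,
    dG_range: tuple[float, float] = (10.0, 50.0),
    sigma: float = 4.0,
    seed: int = 0,
    n_per_direction: int = 500,
    temperature: float = DEFAULT_TEMPERATURE_K,
    calibration: CalibrationModel = CalibrationModel(),
    policy: ClassificationPolicy = ClassificationPolicy(),
    dg_values: Sequence[float] | None = None,
) -> tuple[list[tuple], pd.DataFrame]:
    """A labeled multi-bond panel of work-set pairs plus its truth table.

    True dG values are drawn uniformly in ``dG_range`` unless ``dg_values``
    pins them explicitly (length must equal ``n_bonds``); each bond then
    gets ``n_per_direction`` works per direction from its CFT-consistent
    model.  The truth table carries dG_true and the implied E_cal / E_corr
    / role under the given calibration and policy.

    Returns ``(bonds, truth)`` where each bond is
    ``(bond_id, domain, forward WorkSet, backward WorkSet)``, directly
    consumable by :func:`dsbredox.redox.build_report`.
    """
    if n_bonds < 1:
        raise ValueError(f"n_bonds must be >= 1, got {n_bonds}")
    rng = np.random.default_rng(seed)
    if dg_values is not None:
        if len(dg_values) != n_bonds:
            raise ValueError("dg_values length must equal n_bonds")
        dgs = np.asarray(dg_values, dtype=float)
    else:
        lo, hi = dG_range
        dgs = rng.uniform(lo, hi, size=n_bonds)
    bonds: list[tuple] = []
    rows = []
    for i, dg in enumerate(dgs):
        bond_id = f"bond{i + 1:02d}"
        model = CftModel(
            dG_true=float(dg), sigma=sigma, n_per_direction=n_per_direction,
            temperature=temperature, seed=int(rng.integers(2**31)),
        )
        fwd, bwd = sample_cft_works(model, label=bond_id)
        bonds.append((bond_id, "synthetic", fwd, bwd))
        e_cal = nernst_potential(float(dg))
        e_corr = calibrate(e_cal, calibration)
        rows.append(
            {
                "bond_id": bond_id, "dG_true": float(dg), "sigma": sigma,
                "e_cal_mV": e_cal, "e_corr_mV": e_corr,
                "role": classify(e_corr, policy), "seed": model.seed,
            }
        )
    return bonds, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy structural / topology fixtures (synthetic, deterministic)


def _enumerate_terms(bonds: Sequence[tuple[str, str]]):
    """All angles (3-atom paths) and dihedrals (4-atom paths) of a bond graph."""
    nbrs: dict[str, set[str]] = {}
    for a, b in bonds:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    angles = set()
    for j, js in nbrs.items():
        for i in js:
            for k in js:
                if i < k:
                    angles.add((i, j, k))
    dihedrals = set()
    for j, k in bonds:
        for orient in ((j, k), (k, j)):
            jj, kk = orient
            for i in nbrs[jj] - {kk}:
                for l in nbrs[kk] - {jj}:
                    if i != l:
                        t = (i, jj, kk, l)
                        dihedrals.add(min(t, t[::-1]))
    return tuple(sorted(angles)), tuple(sorted(dihedrals))


_CYS_ATOMS = [
    # name, type, charge (e), mass (u) — synthetic values mimicking the
    # additive-force-field free-cysteine entry; charges sum to zero.
    ("N", "NH1", -0.47, 14.007),
    ("HN", "H", 0.31, 1.008),
    ("CA", "CT1", 0.07, 12.011),
    ("HA", "HB", 0.09, 1.008),
    ("CB", "CT2", -0.11, 12.011),
    ("HB1", "HA", 0.09, 1.008),
    ("HB2", "HA", 0.09, 1.008),
    ("SG", "S", -0.23, 32.06),
    ("HG1", "HS", 0.16, 1.008),
    ("C", "C", 0.51, 12.011),
    ("O", "O", -0.51, 15.999),
]

_CYS_BONDS = [
    ("N", "HN"), ("N", "CA"), ("CA", "HA"), ("CA", "CB"), ("CA", "C"),
    ("CB", "HB1"), ("CB", "HB2"), ("CB", "SG"), ("SG", "HG1"), ("C", "O"),
]

# Half-cystine: no thiol hydrogen; CB/SG charges rebalanced to keep the
# residue neutral, as the disulfide-bonded entry does.
_CYS2_CHARGES = {"CB": -0.10, "SG": -0.08}


def cysteine_template() -> ResidueTemplate:
    """Synthetic free-cysteine (reduced-state) residue template."""
    angles, dihedrals = _enumerate_terms(_CYS_BONDS)
    return ResidueTemplate(
        name="CYS",
        atoms=tuple(TemplateAtom(*a) for a in _CYS_ATOMS),
        bonds=tuple(_CYS_BONDS),
        angles=angles,
        dihedrals=dihedrals,
        formal_charge=0.0,
    )


def cystine_template() -> ResidueTemplate:
    """Synthetic half-cystine (oxidized-state) residue template."""
    atoms = [
        TemplateAtom(n, t, _CYS2_CHARGES.get(n, q), m)
        for n, t, q, m in _CYS_ATOMS
        if n != "HG1"
    ]
    bonds = [b for b in _CYS_BONDS if "HG1" not in b]
    angles, dihedrals = _enumerate_terms(bonds)
    return ResidueTemplate(
        name="CYS2", atoms=tuple(atoms), bonds=tuple(bonds),
        angles=angles, dihedrals=dihedrals, formal_charge=0.0,
    )


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: tuple[float, float, float], element: str,
) -> str:
    namefield = name if len(name) == 4 else f" {name:<3}"
    return (
        f"ATOM  {serial:>5} {namefield}{'':1}{resname:>3} {chain}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2}"
    )


def cysteines_pdb(
    sg_positions: Sequence[tuple[float, float, float]], chain: str = "A"
) -> str:
    """PDB text for a chain of cysteine residues with SG atoms as given.

    Backbone atoms are placed at fixed offsets from each SG; only the SG
    coordinates matter for disulfide detection.
    """
    offsets = {
        "N": (0.0, 2.6, 1.2),
        "CA": (0.0, 1.6, 1.8),
        "CB": (0.0, 0.2, 1.8),
    }
    lines = []
    serial = 1
    for i, sg in enumerate(sg_positions, start=1):
        for name, off in offsets.items():
            xyz = tuple(s + o for s, o in zip(sg, off))
            lines.append(_pdb_atom_line(serial, name, "CYS", chain, i, xyz, name[0]))
            serial += 1
        lines.append(_pdb_atom_line(serial, "SG", "CYS", chain, i, tuple(sg), "S"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def toy_peptide_pdb() -> str:
    """Two-cysteine toy peptide with an SG-SG separation of 2.05 A."""
    return cysteines_pdb([(0.0, 0.0, 0.0), (2.05, 0.0, 0.0)])


def toy_fixtures(directory: str | Path) -> dict[str, Path]:
    """Write the deterministic toy fixtures into ``directory``.

    Emits the two-cysteine peptide (``peptide.pdb``) and the synthetic
    cysteine / half-cystine residue templates (``cys.rtp``, ``cys2.rtp``).
    Returns the paths keyed by fixture name.
    """
    from .topology import write_residue_template

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptide": directory / "peptide.pdb",
        "cysteine": directory / "cys.rtp",
        "cystine": directory / "cys2.rtp",
    }
    paths["peptide"].write_text(toy_peptide_pdb())
    write_residue_template(cysteine_template(), paths["cysteine"])
    write_residue_template(cystine_template(), paths["cystine"])
    return paths
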