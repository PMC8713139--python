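"""Disulfide detection and geometry from PDB coordinates.

Disulfide bonds are located by the standard SG-SG proximity rule (the
covalent S-S bond is ~2.05 A; the default cutoff of 2.5 A comfortably
covers strained geometries without catching non-bonded sulfur contacts).
Distances from each bond to a catalytic-site atom (for LOXL2, the active
site Zn) use the midpoint of the two SG atoms.  Secondary structure is
consumed from an external per-residue annotation, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom
from Bio.PDB.PDBExceptions import PDBConstructionException

#: chain id, author residue number, residue name
ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Raised for unparseable structures or unresolvable selectors."""


@dataclass(frozen=True)
class DisulfideBond:
    """One SG-SG bonded cysteine pair with its geometry."""

    res1: ResidueKey
    res2: ResidueKey
    sg_distance: float
    midpoint: tuple[float, float, float]
    ss1: str = "unknown"
    ss2: str = "unknown"

    @property
    def bond_id(self) -> str:
        return f"{self.res1[2]}{self.res1[1]}-{self.res2[2]}{self.res2[1]}"


@dataclass(frozen=True)
class SiteDistance:
    """Distance from a bond's SG midpoint to a selected site atom."""

    bond: DisulfideBond
    site_atom: tuple[str, int, str]
    distance: float
    per_sg: tuple[float, float] = (0.0, 0.0)


def _resolve_atom(atom):
    """Pick the highest-occupancy altloc of a possibly disordered atom."""
    if isinstance(atom, DisorderedAtom):
        best = max(
            atom.disordered_get_list(),
            key=lambda a: a.get_occupancy() if a.get_occupancy() is not None else 0.0,
        )
        return best
    return atom


def _first_model(pdb: str | Path):
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(Path(pdb).stem, str(pdb))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {pdb}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"no models in PDB file {pdb}")
    return models[0]


def _cys_sg_atoms(model) -> list[tuple[ResidueKey, np.ndarray]]:
    out = []
    for chain in model:
        for res in chain:
            if res.get_resname().strip() != "CYS":
                continue
            if "SG" not in res:
                continue
            atom = _resolve_atom(res["SG"])
            key: ResidueKey = (chain.id, res.id[1], res.get_resname().strip())
            out.append((key, np.asarray(atom.get_coord(), dtype=float)))
    return out


def detect_disulfides(pdb: str | Path, cutoff: float = 2.5) -> list[DisulfideBond]:
    """All disulfide bonds in the first model, by SG-SG proximity.

    Candidate CYS pairs with SG-SG distance <= ``cutoff`` are paired
    greedily by increasing distance, each cysteine joining at most one
    bond.  No cysteines (or none within the cutoff) is an empty list, not
    an error.
    """
    if cutoff <= 0:
        raise StructureError(f"cutoff must be positive, got {cutoff}")
    sgs = _cys_sg_atoms(_first_model(pdb))
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    bonds: list[DisulfideBond] = []
    for d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        (k1, c1), (k2, c2) = sgs[i], sgs[j]
        if (k2[0], k2[1]) < (k1[0], k1[1]):  # order-independent labeling
            (k1, c1), (k2, c2) = (k2, c2), (k1, c1)
        mid = (c1 + c2) / 2.0
        bonds.append(
            DisulfideBond(
                res1=k1, res2=k2, sg_distance=d,
                midpoint=(float(mid[0]), float(mid[1]), float(mid[2])),
            )
        )
    bonds.sort(key=lambda b: (b.res1[0], b.res1[1]))
    return bonds


def parse_site_selector(selector: str) -> tuple[str, int, str]:
    """Parse a ``chain:resnum:atomname`` site selector."""
    parts = selector.split(":")
    if len(parts) != 3:
        raise StructureError(
            f"selector {selector!r} is not of the form chain:resnum:atomname"
        )
    chain, resnum, atomname = parts
    try:
        return chain, int(resnum), atomname
    except ValueError as exc:
        raise StructureError(f"selector {selector!r}: bad residue number") from exc


def site_distances(
    bonds: Sequence[DisulfideBond], pdb: str | Path, site_selector: str
) -> list[SiteDistance]:
    """Distance from each bond's SG midpoint to one selected atom.

    The selector (``chain:resnum:atomname``, HETATM included — e.g. the
    catalytic Zn) must resolve to exactly one atom.
    """
    chain_id, resnum, atomname = parse_site_selector(site_selector)
    model = _first_model(pdb)
    matches = []
    for chain in model:
        if chain.id != chain_id:
            continue
        for res in chain:
            if res.id[1] != resnum:
                continue
            for atom in res:
                if atom.get_name().strip() == atomname:
                    matches.append(_resolve_atom(atom))
    if len(matches) != 1:
        raise StructureError(
            f"selector {site_selector!r} resolved to {len(matches)} atoms (need 1)"
        )
    site = np.asarray(matches[0].get_coord(), dtype=float)

    sg_by_key = {k: c for k, c in _cys_sg_atoms(model)}
    out = []
    for bond in bonds:
        mid = np.asarray(bond.midpoint)
        per_sg = tuple(
            float(np.linalg.norm(sg_by_key[k] - site)) if k in sg_by_key else float("nan")
            for k in (bond.res1, bond.res2)
        )
        out.append(
            SiteDistance(
                bond=bond,
                site_atom=(chain_id, resnum, atomname),
                distance=float(np.linalg.norm(mid - site)),
                per_sg=per_sg,  # type: ignore[arg-type]
            )
        )
    return out


_SS_REDUCE = {
    "H": "H", "G": "H", "I": "H",   # helices
    "E": "E", "B": "E",             # strands/bridges
    "T": "L", "S": "L", "C": "L", "L": "L", "-": "L",
}


def attach_ss_labels(
    bonds: Sequence[DisulfideBond],
    ss_annotation: Mapping[tuple[str, int], str],
) -> list[DisulfideBond]:
    """Attach secondary-structure labels (H/E/L) to each bond's residues.

    The annotation maps (chain, resnum) to a DSSP-style letter, reduced to
    helix/strand/loop; residues absent from the annotation get "unknown".
    """

    def label(key: ResidueKey) -> str:
        raw = ss_annotation.get((key[0], key[1]))
        if raw is None:
            return "unknown"
        return _SS_REDUCE.get(raw.upper(), "unknown")

    return [
        DisulfideBond(
            res1=b.res1, res2=b.res2, sg_distance=b.sg_distance,
            midpoint=b.midpoint, ss1=label(b.res1), ss2=label(b.res2),
        )
        for b in bonds
    ]
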