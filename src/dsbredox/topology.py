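"""Dual-state hybrid residues for alchemical disulfide reduction.

A single-topology alchemical transformation between a disulfide-bonded
cysteine (oxidized, the lambda=0 A-state) and a free cysteine (reduced, the
lambda=1 B-state) needs one residue description carrying both end states.
The hybrid residue (named CYD) is the oxidized cysteine expanded by

* ``HUD`` — a dummy atom, chargeless and interaction-free at lambda=0,
  morphing into the thiol hydrogen at lambda=1;
* ``VC`` and ``VS`` — virtual sites constrained to the positions of the CB
  and S atoms, carrying no charge or dispersion in either state.

Bonded terms that exist only while the S-S bond exists (the S1-S2 bond, the
CB-S-S angles, and the dihedrals whose central axis is S1-S2) are A-state
only and span the two partner residues; they are emitted separately as
cross terms.

Force-field parameters are consumed from user-supplied residue templates; a
minimal synthetic template pair mimicking the cysteine/half-cystine entries
ships with :mod:`dsbredox.synthetic` for testing.  The writer emits a
documented, versioned itp-like dialect with per-state A/B columns; golden
files pin it bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

DIALECT_VERSION = 1

#: Atom-type label designating "no Lennard-Jones interaction".
DUMMY_TYPE = "DUM"
HUD = "HUD"
VSITE_CB = "VC"
VSITE_S = "VS"


class TopologyError(ValueError):
    """Raised for inconsistent templates or hybrid structures."""


@dataclass(frozen=True)
class AtomState:
    """Per-state description of one atom (type, charge in e, mass in u)."""

    type_label: str
    charge: float
    mass: float
    is_dummy: bool = False
    is_virtual_site: bool = False


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    type_label: str
    charge: float
    mass: float


def _norm_bond(t: tuple[str, str]) -> tuple[str, str]:
    return t if t[0] <= t[1] else (t[1], t[0])


def _norm_angle(t: tuple[str, str, str]) -> tuple[str, str, str]:
    return t if t[0] <= t[2] else (t[2], t[1], t[0])


def _norm_dihedral(t: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
    rev = t[::-1]
    return t if t <= rev else rev


@dataclass(frozen=True)
class ResidueTemplate:
    """One residue's atoms and bonded terms (bonds/angles/dihedrals).

    The sum of atomic charges must equal ``formal_charge`` within 1e-6 e.
    Atoms and bonded terms are stored in a canonical order (atoms by name,
    terms normalized direction-independently and sorted), so two templates
    with the same content compare equal.
    """

    name: str
    atoms: tuple[TemplateAtom, ...]
    bonds: tuple[tuple[str, str], ...] = ()
    angles: tuple[tuple[str, str, str], ...] = ()
    dihedrals: tuple[tuple[str, str, str, str], ...] = ()
    formal_charge: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "atoms", tuple(sorted(self.atoms, key=lambda a: a.name))
        )
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise TopologyError(f"{self.name}: duplicate atom names")
        total = sum(a.charge for a in self.atoms)
        if abs(total - self.formal_charge) > 1e-6:
            raise TopologyError(
                f"{self.name}: charge sum {total:.6f} != declared "
                f"formal charge {self.formal_charge:.6f}"
            )
        known = set(names)
        for group in (self.bonds, self.angles, self.dihedrals):
            for term in group:
                unknown = set(term) - known
                if unknown:
                    raise TopologyError(
                        f"{self.name}: bonded term {term} references unknown "
                        f"atom(s) {sorted(unknown)}"
                    )
        object.__setattr__(
            self, "bonds", tuple(sorted(_norm_bond(b) for b in self.bonds))
        )
        object.__setattr__(
            self, "angles", tuple(sorted(_norm_angle(a) for a in self.angles))
        )
        object.__setattr__(
            self, "dihedrals", tuple(sorted(_norm_dihedral(d) for d in self.dihedrals))
        )

    def atom(self, name: str) -> TemplateAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise TopologyError(f"{self.name}: no atom named {name!r}")

    def neighbors(self, name: str) -> set[str]:
        out: set[str] = set()
        for a, b in self.bonds:
            if a == name:
                out.add(b)
            elif b == name:
                out.add(a)
        return out


@dataclass(frozen=True)
class HybridAtom:
    """One hybrid atom with its A (oxidized) and B (reduced) states."""

    name: str
    a: AtomState
    b: AtomState
    position_rule: str | None = None  # anchor atom name for virtual sites


@dataclass(frozen=True)
class BondedTerms:
    bonds: tuple[tuple[str, str], ...] = ()
    angles: tuple[tuple[str, str, str], ...] = ()
    dihedrals: tuple[tuple[str, str, str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "bonds", tuple(sorted(_norm_bond(b) for b in self.bonds)))
        object.__setattr__(self, "angles", tuple(sorted(_norm_angle(a) for a in self.angles)))
        object.__setattr__(
            self, "dihedrals", tuple(sorted(_norm_dihedral(d) for d in self.dihedrals))
        )


@dataclass(frozen=True)
class HybridResidue:
    """Dual-state (A=oxidized, B=reduced) hybrid cysteine description."""

    name: str
    atoms: tuple[HybridAtom, ...]
    bonded_a: BondedTerms
    bonded_b: BondedTerms
    thiol_h_name: str
    sulfur_name: str
    cb_name: str

    def atom(self, name: str) -> HybridAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise TopologyError(f"{self.name}: no atom named {name!r}")


@dataclass(frozen=True)
class CrossBondTerms:
    """Inter-residue bonded terms present only in the oxidized A-state.

    Atom references are prefixed ``1:`` / ``2:`` for the two partner
    residues, e.g. the disulfide bond itself is ``("1:SG", "2:SG")``.
    """

    bond: tuple[str, str]
    angles: tuple[tuple[str, str, str], ...]
    dihedrals: tuple[tuple[str, str, str, str], ...]
    state: Literal["A"] = "A"

    def terms_for_state(self, state: Literal["A", "B"]) -> BondedTerms:
        if state == "A":
            return BondedTerms(bonds=(self.bond,), angles=self.angles,
                               dihedrals=self.dihedrals)
        return BondedTerms()


def build_hybrid_residue(
    cystine_template: ResidueTemplate,
    cysteine_template: ResidueTemplate,
    name: str = "CYD",
) -> HybridResidue:
    """Build the dual-state hybrid from oxidized and reduced templates.

    The reduced (cysteine) template must contain exactly one atom the
    oxidized (half-cystine) template lacks: the thiol hydrogen, realized in
    the hybrid as the dummy HUD.  Any other atom-name difference is a
    structured error listing the offending names.
    """
    ox_names = {a.name for a in cystine_template.atoms}
    red_names = {a.name for a in cysteine_template.atoms}
    extra = red_names - ox_names
    missing = ox_names - red_names
    if missing or len(extra) != 1:
        raise TopologyError(
            "template atom mismatch: only-in-oxidized="
            f"{sorted(missing)} only-in-reduced={sorted(extra)} "
            "(expected exactly one extra reduced atom, the thiol hydrogen)"
        )
    thiol_h = extra.pop()
    s_nbrs = cysteine_template.neighbors(thiol_h)
    if len(s_nbrs) != 1:
        raise TopologyError(f"thiol hydrogen {thiol_h!r} must bond exactly one atom")
    sulfur = s_nbrs.pop()
    cb_candidates = cysteine_template.neighbors(sulfur) - {thiol_h}
    if len(cb_candidates) != 1:
        raise TopologyError(
            f"sulfur {sulfur!r} must have exactly one non-hydrogen neighbor"
        )
    cb = cb_candidates.pop()

    atoms: list[HybridAtom] = []
    for ox_atom in cystine_template.atoms:
        red_atom = cysteine_template.atom(ox_atom.name)
        atoms.append(
            HybridAtom(
                name=ox_atom.name,
                a=AtomState(ox_atom.type_label, ox_atom.charge, ox_atom.mass),
                b=AtomState(red_atom.type_label, red_atom.charge, red_atom.mass),
            )
        )
    th = cysteine_template.atom(thiol_h)
    atoms.append(
        HybridAtom(
            name=HUD,
            a=AtomState(DUMMY_TYPE, 0.0, th.mass, is_dummy=True),
            b=AtomState(th.type_label, th.charge, th.mass),
        )
    )
    for vname, anchor in ((VSITE_CB, cb), (VSITE_S, sulfur)):
        vs = AtomState(DUMMY_TYPE, 0.0, 0.0, is_virtual_site=True)
        atoms.append(HybridAtom(name=vname, a=vs, b=vs, position_rule=anchor))

    def _rename(term: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(HUD if x == thiol_h else x for x in term)

    bonded_b = BondedTerms(
        bonds=tuple(_rename(b) for b in cysteine_template.bonds),  # type: ignore[arg-type]
        angles=tuple(_rename(a) for a in cysteine_template.angles),  # type: ignore[arg-type]
        dihedrals=tuple(_rename(d) for d in cysteine_template.dihedrals),  # type: ignore[arg-type]
    )
    return HybridResidue(
        name=name,
        atoms=tuple(atoms),
        bonded_a=BondedTerms(
            bonds=cystine_template.bonds,
            angles=cystine_template.angles,
            dihedrals=cystine_template.dihedrals,
        ),
        bonded_b=bonded_b,
        thiol_h_name=thiol_h,
        sulfur_name=sulfur,
        cb_name=cb,
    )


def project_state(hybrid: HybridResidue, state: Literal["A", "B"],
                  name: str | None = None) -> ResidueTemplate:
    """Collapse a hybrid to one end state's plain residue template.

    The A-projection drops HUD and the virtual sites; the B-projection
    drops the virtual sites and realizes HUD as the thiol hydrogen.
    """
    atoms: list[TemplateAtom] = []
    for ha in hybrid.atoms:
        st = ha.a if state == "A" else ha.b
        if st.is_virtual_site:
            continue
        if state == "A" and ha.name == HUD:
            continue
        aname = hybrid.thiol_h_name if (state == "B" and ha.name == HUD) else ha.name
        atoms.append(TemplateAtom(aname, st.type_label, st.charge, st.mass))

    terms = hybrid.bonded_a if state == "A" else hybrid.bonded_b

    def _rename(term: tuple[str, ...]) -> tuple[str, ...]:
        if state == "A":
            return term
        return tuple(hybrid.thiol_h_name if x == HUD else x for x in term)

    total = sum(a.charge for a in atoms)
    return ResidueTemplate(
        name=name if name is not None else hybrid.name,
        atoms=tuple(atoms),
        bonds=tuple(_rename(b) for b in terms.bonds),  # type: ignore[arg-type]
        angles=tuple(_rename(a) for a in terms.angles),  # type: ignore[arg-type]
        dihedrals=tuple(_rename(d) for d in terms.dihedrals),  # type: ignore[arg-type]
        formal_charge=round(total, 6),
    )


def pair_cross_terms(res1: HybridResidue, res2: HybridResidue) -> CrossBondTerms:
    """Oxidized-state-only terms tying two hybrid cysteines together.

    Emits the S1-S2 bond, the two CB-S-S angles, and every dihedral whose
    central axis is the S1-S2 bond, found by enumerating 4-atom paths
    X-S1-S2-Y over the residues' A-state connectivity.  All terms are
    A-state only: at lambda=1 the two cysteines are independent.
    """
    for res in (res1, res2):
        if res.name != "CYD":
            raise TopologyError(
                f"cross terms are defined for CYD hybrids, got {res.name!r}"
            )
    s1, s2 = f"1:{res1.sulfur_name}", f"2:{res2.sulfur_name}"

    def _a_neighbors(res: HybridResidue, prefix: str) -> list[str]:
        nbrs: set[str] = set()
        for a, b in res.bonded_a.bonds:
            if a == res.sulfur_name:
                nbrs.add(b)
            elif b == res.sulfur_name:
                nbrs.add(a)
        return sorted(f"{prefix}:{n}" for n in nbrs)

    nbr1 = _a_neighbors(res1, "1")
    nbr2 = _a_neighbors(res2, "2")
    angles = (
        (f"1:{res1.cb_name}", s1, s2),
        (f"2:{res2.cb_name}", s2, s1),
    )
    dihedrals = tuple(sorted((x, s1, s2, y) for x in nbr1 for y in nbr2))
    return CrossBondTerms(bond=(s1, s2), angles=angles, dihedrals=dihedrals)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationItem:
    check: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    items: tuple[ValidationItem, ...]

    @property
    def n_failed(self) -> int:
        return sum(1 for i in self.items if not i.passed)

    @property
    def passed(self) -> bool:
        return self.n_failed == 0


def validate_state_equivalence(
    hybrid: HybridResidue,
    cystine: ResidueTemplate,
    cysteine: ResidueTemplate,
) -> ValidationReport:
    """Itemized end-state fidelity checks for a hybrid residue.

    Checks are disjoint: projection checks cover only template atoms and
    terms, dummy/virtual-site checks cover only the added atoms, and charge
    sums are taken over the projections.
    """
    items: list[ValidationItem] = []

    def add(check: str, passed: bool, detail: str = "") -> None:
        items.append(ValidationItem(check, bool(passed), detail))

    proj_a = project_state(hybrid, "A", name=cystine.name)
    proj_b = project_state(hybrid, "B", name=cysteine.name)

    add("A_atoms_match_cystine", proj_a.atoms == cystine.atoms,
        f"{proj_a.atoms} vs {cystine.atoms}")
    add("A_bonded_match_cystine",
        (proj_a.bonds, proj_a.angles, proj_a.dihedrals)
        == (cystine.bonds, cystine.angles, cystine.dihedrals))
    add("B_atoms_match_cysteine", proj_b.atoms == cysteine.atoms,
        f"{proj_b.atoms} vs {cysteine.atoms}")
    add("B_bonded_match_cysteine",
        (proj_b.bonds, proj_b.angles, proj_b.dihedrals)
        == (cysteine.bonds, cysteine.angles, cysteine.dihedrals))

    hud = hybrid.atom(HUD)
    add("HUD_A_state_neutral_dummy",
        hud.a.charge == 0.0 and hud.a.type_label == DUMMY_TYPE)
    flat_a = [x for g in (hybrid.bonded_a.bonds, hybrid.bonded_a.angles,
                          hybrid.bonded_a.dihedrals) for t in g for x in t]
    add("HUD_absent_from_A_bonded", HUD not in flat_a)
    flat_b = [x for g in (hybrid.bonded_b.bonds, hybrid.bonded_b.angles,
                          hybrid.bonded_b.dihedrals) for t in g for x in t]
    add("HUD_present_in_B_bonded", HUD in flat_b)

    for vname in (VSITE_CB, VSITE_S):
        va = hybrid.atom(vname)
        add(f"{vname}_interaction_free",
            va.a.charge == 0.0 and va.b.charge == 0.0
            and va.a.type_label == DUMMY_TYPE and va.b.type_label == DUMMY_TYPE
            and va.position_rule is not None)
    add("VC_anchored_to_CB", hybrid.atom(VSITE_CB).position_rule == hybrid.cb_name)
    add("VS_anchored_to_S", hybrid.atom(VSITE_S).position_rule == hybrid.sulfur_name)
    return ValidationReport(items=tuple(items))


# ---------------------------------------------------------------------------
# Residue-template text format (rtp-like)


def write_residue_template(template: ResidueTemplate, path: str | Path) -> None:
    lines = [
        f"; dsbredox residue template v{DIALECT_VERSION}",
        f"[ residue {template.name} charge {template.formal_charge!r} ]",
        "[ atoms ]",
    ]
    for a in template.atoms:
        lines.append(f"{a.name} {a.type_label} {a.charge!r} {a.mass!r}")
    for section, terms in (
        ("bonds", template.bonds),
        ("angles", template.angles),
        ("dihedrals", template.dihedrals),
    ):
        lines.append(f"[ {section} ]")
        lines.extend(" ".join(t) for t in terms)
    Path(path).write_text("\n".join(lines) + "\n")


def read_residue_template(path: str | Path) -> ResidueTemplate:
    name = ""
    formal = 0.0
    section = ""
    atoms: list[TemplateAtom] = []
    terms: dict[str, list[tuple[str, ...]]] = {"bonds": [], "angles": [], "dihedrals": []}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            tokens = line.strip("[] ").split()
            if tokens[0] == "residue":
                name = tokens[1]
                formal = float(tokens[3])
            else:
                section = tokens[0]
            continue
        tokens = line.split()
        try:
            if section == "atoms":
                atoms.append(
                    TemplateAtom(tokens[0], tokens[1], float(tokens[2]), float(tokens[3]))
                )
            elif section in terms:
                terms[section].append(tuple(tokens))
            else:
                raise TopologyError(f"{path}: line {lineno}: data outside a section")
        except (IndexError, ValueError) as exc:
            raise TopologyError(f"{path}: line {lineno}: malformed entry") from exc
    return ResidueTemplate(
        name=name, atoms=tuple(atoms),
        bonds=tuple(terms["bonds"]),  # type: ignore[arg-type]
        angles=tuple(terms["angles"]),  # type: ignore[arg-type]
        dihedrals=tuple(terms["dihedrals"]),  # type: ignore[arg-type]
        formal_charge=formal,
    )


# ---------------------------------------------------------------------------
# Perturbed-topology dialect (A/B columns)


def _merge_states(a_terms: tuple, b_terms: tuple) -> list[tuple[tuple[str, ...], str]]:
    a_set, b_set = set(a_terms), set(b_terms)
    merged = sorted(a_set | b_set)
    out = []
    for t in merged:
        state = "AB" if t in a_set and t in b_set else ("A" if t in a_set else "B")
        out.append((t, state))
    return out


def write_perturbed_topology(
    residues: Sequence[HybridResidue],
    cross: Sequence[CrossBondTerms],
    path: str | Path,
) -> None:
    """Write hybrids + cross terms in the package's A/B-column dialect.

    Per-atom lines carry (type, charge, mass) for each state plus a flag
    column; per-term lines carry a state column ``A``/``B``/``AB`` — an
    A-only term has no B-state parameters, per the dialect rule.  Output is
    deterministic and round-trips through :func:`read_perturbed_topology`.
    """
    lines = [f"; dsbredox perturbed topology dialect v{DIALECT_VERSION}"]
    for idx, res in enumerate(residues, start=1):
        lines.append(f"[ hybrid {res.name} {idx} ]")
        lines.append(f"[ meta thiol_h {res.thiol_h_name} sulfur {res.sulfur_name} "
                     f"cb {res.cb_name} ]")
        lines.append("[ atoms ]")
        lines.append("; name typeA chargeA massA typeB chargeB massB flag")
        for ha in res.atoms:
            if ha.position_rule is not None:
                flag = f"vsite={ha.position_rule}"
            elif ha.a.is_dummy or ha.b.is_dummy:
                flag = "dummyA"
            else:
                flag = "-"
            lines.append(
                f"{ha.name} {ha.a.type_label} {ha.a.charge!r} {ha.a.mass!r} "
                f"{ha.b.type_label} {ha.b.charge!r} {ha.b.mass!r} {flag}"
            )
        for section, a_terms, b_terms in (
            ("bonds", res.bonded_a.bonds, res.bonded_b.bonds),
            ("angles", res.bonded_a.angles, res.bonded_b.angles),
            ("dihedrals", res.bonded_a.dihedrals, res.bonded_b.dihedrals),
        ):
            lines.append(f"[ {section} ]")
            for term, state in _merge_states(a_terms, b_terms):
                lines.append(" ".join(term) + f" {state}")
    for ct in cross:
        lines.append("[ cross 1 2 ]")
        lines.append("bond " + " ".join(ct.bond) + " A")
        for ang in ct.angles:
            lines.append("angle " + " ".join(ang) + " A")
        for dih in ct.dihedrals:
            lines.append("dihedral " + " ".join(dih) + " A")
    Path(path).write_text("\n".join(lines) + "\n")


def read_perturbed_topology(
    path: str | Path,
) -> tuple[list[HybridResidue], list[CrossBondTerms]]:
    """Parse the A/B-column dialect back into hybrids and cross terms."""
    residues: list[HybridResidue] = []
    cross: list[CrossBondTerms] = []
    cur: dict | None = None
    cur_cross: dict | None = None
    section = ""

    def _flush_res() -> None:
        nonlocal cur
        if cur is None:
            return
        residues.append(
            HybridResidue(
                name=cur["name"],
                atoms=tuple(cur["atoms"]),
                bonded_a=BondedTerms(
                    bonds=tuple(cur["A"]["bonds"]),
                    angles=tuple(cur["A"]["angles"]),
                    dihedrals=tuple(cur["A"]["dihedrals"]),
                ),
                bonded_b=BondedTerms(
                    bonds=tuple(cur["B"]["bonds"]),
                    angles=tuple(cur["B"]["angles"]),
                    dihedrals=tuple(cur["B"]["dihedrals"]),
                ),
                thiol_h_name=cur["meta"]["thiol_h"],
                sulfur_name=cur["meta"]["sulfur"],
                cb_name=cur["meta"]["cb"],
            )
        )
        cur = None

    def _flush_cross() -> None:
        nonlocal cur_cross
        if cur_cross is None:
            return
        cross.append(
            CrossBondTerms(
                bond=cur_cross["bond"],
                angles=tuple(cur_cross["angles"]),
                dihedrals=tuple(cur_cross["dihedrals"]),
            )
        )
        cur_cross = None

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            tokens = line.strip("[] ").split()
            if tokens[0] == "hybrid":
                _flush_res()
                _flush_cross()
                cur = {
                    "name": tokens[1], "atoms": [], "meta": {},
                    "A": {"bonds": [], "angles": [], "dihedrals": []},
                    "B": {"bonds": [], "angles": [], "dihedrals": []},
                }
            elif tokens[0] == "meta":
                assert cur is not None
                cur["meta"] = dict(zip(tokens[1::2], tokens[2::2]))
            elif tokens[0] == "cross":
                _flush_res()
                _flush_cross()
                cur_cross = {"bond": None, "angles": [], "dihedrals": []}
            else:
                section = tokens[0]
            continue
        tokens = line.split()
        if cur_cross is not None:
            kind, term = tokens[0], tuple(tokens[1:-1])
            if kind == "bond":
                cur_cross["bond"] = term
            elif kind == "angle":
                cur_cross["angles"].append(term)
            elif kind == "dihedral":
                cur_cross["dihedrals"].append(term)
            else:
                raise TopologyError(f"{path}: line {lineno}: unknown cross term {kind!r}")
            continue
        if cur is None:
            raise TopologyError(f"{path}: line {lineno}: data outside a section")
        if section == "atoms":
            try:
                name, ta, ca, ma, tb, cb_, mb, flag = tokens
            except ValueError as exc:
                raise TopologyError(f"{path}: line {lineno}: malformed atom line") from exc
            vsite = flag.startswith("vsite=")
            rule = flag.split("=", 1)[1] if vsite else None
            dummy = flag == "dummyA"
            cur["atoms"].append(
                HybridAtom(
                    name=name,
                    a=AtomState(ta, float(ca), float(ma), is_dummy=dummy,
                                is_virtual_site=vsite),
                    b=AtomState(tb, float(cb_), float(mb), is_virtual_site=vsite),
                    position_rule=rule,
                )
            )
        elif section in ("bonds", "angles", "dihedrals"):
            term, state = tuple(tokens[:-1]), tokens[-1]
            if state in ("A", "AB"):
                cur["A"][section].append(term)
            if state in ("B", "AB"):
                cur["B"][section].append(term)
        else:
            raise TopologyError(f"{path}: line {lineno}: unknown section {section!r}")
    _flush_res()
    _flush_cross()
    return residues, cross
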