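"""Ensemble superposition, side-chain conformer measurement, and the
cross-protomer hydrogen-bond census.

Crystal structures of the same protein deposit many independent copies
(protomers) of the subunit; superposing them onto one reference exposes
the ensemble of side-chain conformers at a position, and counting each
protomer's best hydrogen-bond partner for a donor atom summarises how a
contact is distributed across the ensemble.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .contacts import HbondCriteria, hbond_geometry_ok
from .geometry import DegenerateGeometryError, Transform, dihedral, kabsch_superpose
from .residues import CHI_ATOMS, SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS, BACKBONE_DONOR
from .rotamers import ChiAngles
from .structure import Protomer, Residue

__all__ = [
    "Selection",
    "kabsch_superpose",
    "Transform",
    "superpose_ensemble",
    "measure_chi",
    "measure_phi_psi",
    "AtomSpec",
    "HbondCensus",
    "census_hbonds",
]


@dataclass(frozen=True)
class Selection:
    """Atom selection for superposition: residue range + atom-name filter.

    String syntax: ``chain:start-end@ATOM,ATOM`` with every part optional,
    e.g. ``A:1-10@N,CA,C,O``, ``5-20``, ``@CA``.
    """

    chain_id: str | None = None
    start: int | None = None
    end: int | None = None
    atom_names: tuple[str, ...] = ("N", "CA", "C", "O")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        m = re.fullmatch(
            r"(?:(?P<chain>[A-Za-z0-9]+):)?(?:(?P<start>-?\d+)-(?P<end>-?\d+))?"
            r"(?:@(?P<atoms>[A-Za-z0-9',]+))?",
            text.strip(),
        )
        if m is None:
            raise ValueError(f"cannot parse selection {text!r}")
        atoms = m.group("atoms")
        return cls(
            chain_id=m.group("chain"),
            start=int(m.group("start")) if m.group("start") else None,
            end=int(m.group("end")) if m.group("end") else None,
            atom_names=tuple(atoms.split(",")) if atoms else ("N", "CA", "C", "O"),
        )

    def resolve(self, protomer: Protomer) -> list[tuple[int, str]]:
        """(residue number, atom name) pairs the selection covers in a
        protomer; raises if nothing matches or an atom is missing."""
        if self.chain_id is not None and protomer.chain_id != self.chain_id:
            return []
        pairs = []
        for res in protomer.residues:
            if self.start is not None and res.number < self.start:
                continue
            if self.end is not None and res.number > self.end:
                continue
            for name in self.atom_names:
                if not res.has_atom(name):
                    raise KeyError(
                        f"selection atom {name} missing in chain {protomer.chain_id} "
                        f"residue {res.amino_acid}{res.number}"
                    )
                pairs.append((res.number, name))
        return pairs


def _coords_for(protomer: Protomer, pairs: list[tuple[int, str]]) -> np.ndarray:
    return np.array(
        [protomer.residue(num).atom(name).position for num, name in pairs]
    )


def superpose_ensemble(
    protomers: list[Protomer],
    reference_index: int = 0,
    selection: Selection | str | None = None,
) -> tuple[list[Protomer], list[float]]:
    """Superpose every protomer onto the reference over the selection.

    Returns transformed copies (reference included, untouched) and the
    per-protomer RMSD over the selected atoms.
    """
    if not protomers:
        raise ValueError("empty ensemble")
    if isinstance(selection, str):
        selection = Selection.parse(selection)
    selection = selection or Selection()
    reference = protomers[reference_index]
    ref_pairs = selection.resolve(reference)
    if not ref_pairs:
        raise ValueError("selection resolves to no atoms in the reference protomer")
    ref_xyz = _coords_for(reference, ref_pairs)
    out: list[Protomer] = []
    rmsds: list[float] = []
    for k, prot in enumerate(protomers):
        if k == reference_index:
            out.append(prot.copy())
            rmsds.append(0.0)
            continue
        pairs = [(num, name) for num, name in ref_pairs]
        for num, name in pairs:
            if not prot.has_residue(num):
                raise KeyError(
                    f"protomer {prot.chain_id!r} (index {k}) lacks residue {num} "
                    "required by the selection"
                )
        mob_xyz = _coords_for(prot, pairs)
        # sequence agreement over the paired positions
        for num, _ in pairs:
            if prot.residue(num).amino_acid != reference.residue(num).amino_acid:
                raise ValueError(
                    f"residue {num} differs between reference "
                    f"({reference.residue(num).amino_acid}) and protomer {k} "
                    f"({prot.residue(num).amino_acid})"
                )
        transform, rmsd = kabsch_superpose(mob_xyz, ref_xyz)
        moved = prot.copy()
        for res in moved.residues:
            for atom in res.atoms:
                atom.position = transform.apply(atom.position)
        out.append(moved)
        rmsds.append(rmsd)
    return out, rmsds


def measure_chi(residue: Residue) -> ChiAngles:
    """Measure the side-chain chi dihedrals of a residue.

    Gly/Ala give empty ChiAngles. Missing defining atoms raise KeyError
    naming the chi index and atom; collinear geometry raises
    DegenerateGeometryError.
    """
    aa = residue.amino_acid.upper()
    defs = CHI_ATOMS.get(aa)
    if defs is None:
        raise KeyError(f"no chi definition for residue type {aa!r}")
    values = []
    for k, names in enumerate(defs, start=1):
        pts = []
        for name in names:
            if not residue.has_atom(name):
                raise KeyError(
                    f"chi{k} of {aa}{residue.number}: missing atom {name}"
                )
            pts.append(residue.atom(name).position)
        try:
            values.append(dihedral(*pts))
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(
                f"chi{k} of {aa}{residue.number} undefined: {exc}"
            ) from exc
    return ChiAngles(tuple(values), aa)


def measure_phi_psi(protomer: Protomer, position: int) -> tuple[float | None, float | None]:
    """Backbone (phi, psi) of a residue; None at chain termini."""
    idx = next(
        i for i, r in enumerate(protomer.residues) if r.number == position
    )
    res = protomer.residues[idx]
    phi = psi = None
    if idx > 0 and protomer.residues[idx - 1].number == position - 1:
        prev = protomer.residues[idx - 1]
        phi = dihedral(
            prev.atom("C").position, res.atom("N").position,
            res.atom("CA").position, res.atom("C").position,
        )
    if idx + 1 < len(protomer.residues) and protomer.residues[idx + 1].number == position + 1:
        nxt = protomer.residues[idx + 1]
        psi = dihedral(
            res.atom("N").position, res.atom("CA").position,
            res.atom("C").position, nxt.atom("N").position,
        )
    return phi, psi


# --- hydrogen-bond census --------------------------------------------------

@dataclass(frozen=True)
class AtomSpec:
    """A residue+atom reference for the census: a specific atom name, or
    ``atom=None`` meaning the residue's side-chain donor/acceptor atoms."""

    residue_number: int
    atom: str | None = None

    def label(self, residue: Residue) -> str:
        base = f"{residue.amino_acid}{residue.number}"
        return base if self.atom is None else f"{base}:{self.atom}"


@dataclass
class HbondCensus:
    """Per-acceptor counts of a donor's best hydrogen-bond partner across
    an ensemble; ``partner_counts`` includes the key "none"."""

    donor: str
    partner_counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    excluded_protomers: list[int] = field(default_factory=list)

    def check(self):
        if sum(self.partner_counts.values()) != self.total:
            raise AssertionError("census counts do not sum to total")


def _donor_antecedent(residue: Residue, atom_name: str) -> str:
    if atom_name == BACKBONE_DONOR[0]:
        return BACKBONE_DONOR[1]
    for name, ante in SIDECHAIN_DONORS.get(residue.amino_acid, []):
        if name == atom_name:
            return ante
    raise KeyError(
        f"{residue.amino_acid}{residue.number}:{atom_name} is not a known donor"
    )


def _acceptor_atoms(residue: Residue, spec: AtomSpec) -> list[str]:
    if spec.atom is not None:
        return [spec.atom] if residue.has_atom(spec.atom) else []
    return [
        name
        for name, _ante in SIDECHAIN_ACCEPTORS.get(residue.amino_acid, [])
        if residue.has_atom(name)
    ]


def census_hbonds(
    ensemble: list[Protomer],
    donor: AtomSpec,
    candidate_acceptors: list[AtomSpec],
    criteria: HbondCriteria | None = None,
) -> HbondCensus:
    """Assign each protomer's donor its best-satisfying acceptor (or
    "none") and count the partition across the ensemble.

    The best acceptor is the criteria-satisfying candidate at minimal
    donor-acceptor distance; exact ties break by label lexicographic
    order. Protomers lacking the donor atom are excluded and reported.
    """
    if donor.atom is None:
        raise ValueError("census donor must name a specific atom")
    criteria = criteria or HbondCriteria()
    counts: dict[str, int] = {}
    excluded: list[int] = []
    total = 0
    donor_label = None
    for k, prot in enumerate(ensemble):
        try:
            dres = prot.residue(donor.residue_number)
            datom = dres.atom(donor.atom)
        except KeyError:
            excluded.append(k)
            continue
        if donor_label is None:
            donor_label = donor.label(dres)
        dante = dres.atom(_donor_antecedent(dres, donor.atom))
        best: tuple[float, str] | None = None
        for spec in candidate_acceptors:
            try:
                ares = prot.residue(spec.residue_number)
            except KeyError:
                continue
            for aname in _acceptor_atoms(ares, spec):
                ok, dist, _ang = hbond_geometry_ok(
                    datom, dante, ares.atom(aname), criteria
                )
                if not ok:
                    continue
                cand = (dist, spec.label(ares))
                if best is None or cand < best:
                    best = cand
        partner = best[1] if best is not None else "none"
        counts[partner] = counts.get(partner, 0) + 1
        total += 1
    census = HbondCensus(
        donor=donor_label or f"residue {donor.residue_number}:{donor.atom}",
        partner_counts=counts,
        total=total,
        excluded_protomers=excluded,
    )
    census.check()
    return census
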