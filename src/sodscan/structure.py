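"""Coordinate data model and PDB/mmCIF readers-writers.

The in-memory model is deliberately small: ``Structure`` holds
``Protomer`` chains of ``Residue`` objects holding ``Atom`` records with
element identity and an element-derived van der Waals radius. Parsing and
serialisation of the wwPDB formats is delegated to gemmi; this module only
applies the package's conventions on top (first model, altloc A/blank,
author numbering kept verbatim, Bondi radii on heavy atoms).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .residues import DEFAULT_VDW_RADII

__all__ = [
    "Atom",
    "Residue",
    "Protomer",
    "Structure",
    "ParseError",
    "parse_structure",
    "parse_structure_file",
    "assign_vdw_radii",
    "write_pdb",
    "load_radius_table",
]

logger = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """Malformed coordinate input or invariant violation while parsing."""


@dataclass
class Atom:
    """One heavy atom (or optionally hydrogen) with coordinates in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    vdw_radius: float | None = None
    is_hydrogen: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    """One residue, author-numbered, holding uniquely named atoms."""

    number: int
    amino_acid: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.name, a.altloc)
            if key in seen:
                raise ParseError(
                    f"residue {self.amino_acid}{self.number}: duplicate atom {key}"
                )
            seen.add(key)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.amino_acid}{self.number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_complete_backbone(self) -> bool:
        return all(self.has_atom(n) for n in BACKBONE_NAMES)

    def backbone(self) -> dict[str, Atom]:
        """N, CA, C, O and CB if present."""
        out = {}
        for n in (*BACKBONE_NAMES, "CB"):
            if self.has_atom(n):
                out[n] = self.atom(n)
        return out

    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms beyond the backbone, CB included."""
        bb = set(BACKBONE_NAMES) | {"OXT"}
        return [a for a in self.atoms if a.name not in bb and not a.is_hydrogen]

    def coords(self, names: list[str] | None = None) -> np.ndarray:
        atoms = self.atoms if names is None else [self.atom(n) for n in names]
        return np.array([a.position for a in atoms])

    def copy(self) -> "Residue":
        return Residue(
            number=self.number,
            amino_acid=self.amino_acid,
            atoms=[a.copy() for a in self.atoms],
            insertion_code=self.insertion_code,
        )


@dataclass
class Protomer:
    """One chain instance (subunit) of a structure."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        keys = [(r.number, r.insertion_code) for r in self.residues]
        for prev, cur in zip(keys, keys[1:]):
            if cur <= prev:
                raise ParseError(
                    f"chain {self.chain_id}: residue numbering not increasing at {cur}"
                )

    def residue(self, number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"chain {self.chain_id} has no residue {number}{insertion_code}")

    def has_residue(self, number: int) -> bool:
        return any(r.number == number for r in self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def copy(self) -> "Protomer":
        return Protomer(
            chain_id=self.chain_id,
            residues=[r.copy() for r in self.residues],
            source=self.source,
        )


@dataclass
class Structure:
    accession: str
    protomers: list[Protomer] = field(default_factory=list)
    resolution: float | None = None

    def __post_init__(self):
        if not self.protomers:
            raise ParseError(f"structure {self.accession!r} contains no protomers")

    def protomer(self, chain_id: str) -> Protomer:
        for p in self.protomers:
            if p.chain_id == chain_id:
                return p
        raise KeyError(f"no chain {chain_id!r} in {self.accession}")


def load_radius_table(path) -> dict[str, float]:
    """Read an element -> radius (Angstrom) map from a JSON config file."""
    with open(path) as fh:
        table = json.load(fh)
    return {str(k).upper(): float(v) for k, v in table.items()}


def _from_gemmi(st: gemmi.Structure, accession: str) -> Structure:
    """Convert model 1 of a gemmi structure, applying the altloc policy."""
    if len(st) == 0:
        raise ParseError(f"{accession}: no models in input")
    model = st[0]
    n_discarded = 0
    protomers = []
    for chain in model:
        residues = []
        for res in chain:
            atoms = []
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    n_discarded += 1
                    continue
                elem = at.element.name.upper()
                if not elem or elem == "X":
                    raise ParseError(
                        f"{accession}: unknown element for atom {at.name} in "
                        f"{res.name}{res.seqid.num} chain {chain.name}"
                    )
                atoms.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        altloc="" if at.altloc in ("\0", "A") else at.altloc,
                        occupancy=at.occ,
                        is_hydrogen=elem in ("H", "D"),
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    number=res.seqid.num,
                    amino_acid=res.name,
                    atoms=atoms,
                    insertion_code=(res.seqid.icode or "").strip(),
                )
            )
        if residues:
            protomers.append(
                Protomer(
                    chain_id=chain.name,
                    residues=residues,
                    source=f"{accession}/model1",
                )
            )
    if n_discarded:
        logger.info("%s: discarded %d non-A altloc atoms", accession, n_discarded)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    structure = Structure(accession=accession, protomers=protomers, resolution=resolution)
    return assign_vdw_radii(structure, DEFAULT_VDW_RADII)


def parse_structure(text: str, format: str = "pdb", accession: str = "input") -> Structure:
    """Parse PDB or mmCIF text into a Structure.

    Keeps the first model only and altloc A/blank atoms; assigns Bondi
    radii to every heavy atom. ``format`` is ``"pdb"`` or ``"mmcif"``.
    """
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt in ("mmcif", "cif"):
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {format!r}; use 'pdb' or 'mmcif'")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ParseError(f"{accession}: failed to parse {fmt} input: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, accession)


def parse_structure_file(path, format: str | None = None) -> Structure:
    """Parse a coordinate file, inferring the format from the suffix if
    not given."""
    path = str(path)
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    with open(path) as fh:
        text = fh.read()
    name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return parse_structure(text, format=format, accession=name)


def assign_vdw_radii(structure: Structure, radius_table: dict[str, float]) -> Structure:
    """Assign element-derived van der Waals radii to all heavy atoms.

    Hydrogens stay radius-less. Raises ParseError listing the elements the
    table does not cover.
    """
    table = {k.upper(): float(v) for k, v in radius_table.items()}
    missing = set()
    for prot in structure.protomers:
        for res in prot.residues:
            for atom in res.atoms:
                if atom.is_hydrogen:
                    atom.vdw_radius = None
                    continue
                r = table.get(atom.element)
                if r is None:
                    missing.add(atom.element)
                else:
                    atom.vdw_radius = r
    if missing:
        raise ParseError(
            "radius table does not cover element(s): " + ", ".join(sorted(missing))
        )
    return structure


def write_pdb(structure: Structure) -> str:
    """Serialise a Structure to PDB text (via gemmi's writer)."""
    st = gemmi.Structure()
    st.name = structure.accession
    model = gemmi.Model("1")
    for prot in structure.protomers:
        chain = gemmi.Chain(prot.chain_id)
        for res in prot.residues:
            gres = gemmi.Residue()
            gres.name = res.amino_acid
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.altloc = atom.altloc or "\0"
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
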