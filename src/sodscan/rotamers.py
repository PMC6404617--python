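"""Rotamer enumeration and ideal-geometry side-chain construction.

A substitution is modelled by deleting the template side chain and
rebuilding the target amino acid's heavy atoms on the fixed backbone from
ideal internal coordinates (bond length, bond angle, dihedral), with the
chi dihedrals set to a candidate rotamer. Candidates come either from a
compact shipped library of modal chi values or from an exhaustive chi grid
("all possible rotamers"); both are enumerated in a fixed order so scans
are deterministic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import place_atom, wrap_angle
from .residues import CB_PLACEMENT, CHI_ATOMS, DEFAULT_VDW_RADII, SIDECHAIN_RECIPES, STANDARD_AA, chi_count
from .structure import Atom, Protomer, Residue

__all__ = [
    "ChiAngles",
    "Rotamer",
    "RotamerLibrary",
    "VariantSpec",
    "DELETION",
    "load_default_library",
    "enumerate_rotamers",
    "grid_rotamers",
    "build_side_chain",
    "replace_residue",
]

DELETION = "DEL"


@dataclass(frozen=True)
class ChiAngles:
    """Ordered side-chain dihedrals in degrees, each in (-180, 180]."""

    values: tuple[float, ...]
    amino_acid: str

    def __post_init__(self):
        aa = self.amino_acid.upper()
        expected = chi_count(aa)
        if len(self.values) != expected:
            raise ValueError(
                f"{aa} has {expected} chi angles, got {len(self.values)}"
            )
        object.__setattr__(self, "amino_acid", aa)
        object.__setattr__(self, "values", tuple(wrap_angle(v) for v in self.values))


@dataclass(frozen=True)
class Rotamer:
    amino_acid: str
    chi: ChiAngles
    source: str = "library"  # "library" or "grid"
    label: str = ""

    def __post_init__(self):
        if self.chi.amino_acid != self.amino_acid.upper():
            raise ValueError("rotamer amino acid does not match its chi angles")
        object.__setattr__(self, "amino_acid", self.amino_acid.upper())


@dataclass
class RotamerLibrary:
    entries: dict[str, list[Rotamer]]
    backbone_dependent: bool = False
    phi_psi_bin_deg: float = 20.0

    def __post_init__(self):
        for aa in STANDARD_AA:
            if aa not in self.entries or not self.entries[aa]:
                raise ValueError(f"rotamer library has no entry for {aa}")


def load_default_library() -> RotamerLibrary:
    """Load the shipped compact modal-chi library."""
    with resources.files("sodscan.data").joinpath("rotamer_library.json").open() as fh:
        raw = json.load(fh)
    entries = {
        aa: [
            Rotamer(
                amino_acid=aa,
                chi=ChiAngles(tuple(e["chi"]), aa),
                source="library",
                label=e.get("label", ""),
            )
            for e in lst
        ]
        for aa, lst in raw["entries"].items()
    }
    return RotamerLibrary(
        entries=entries,
        backbone_dependent=bool(raw.get("backbone_dependent", False)),
        phi_psi_bin_deg=float(raw.get("phi_psi_bin_deg", 20.0)),
    )


@dataclass(frozen=True)
class VariantSpec:
    """A point substitution or deletion, e.g. E40G or E133del."""

    position: int
    wild_type: str
    substitution: str  # 3-letter code or DELETION

    def __post_init__(self):
        object.__setattr__(self, "wild_type", self.wild_type.upper())
        sub = self.substitution.upper()
        if sub in ("DEL", "DELETION"):
            sub = DELETION
        object.__setattr__(self, "substitution", sub)
        if self.wild_type not in STANDARD_AA:
            raise ValueError(f"unknown wild-type residue {self.wild_type!r}")
        if sub != DELETION and sub not in STANDARD_AA:
            raise ValueError(f"unknown substitution {sub!r}")

    @property
    def is_deletion(self) -> bool:
        return self.substitution == DELETION

    @classmethod
    def from_string(cls, text: str) -> "VariantSpec":
        """Parse compact notation like ``E40G``, ``E133del``, ``E133Del``."""
        from .residues import AA_ONE_TO_THREE

        t = text.strip()
        if len(t) < 3 or not t[0].isalpha():
            raise ValueError(f"cannot parse variant {text!r}")
        wt1 = t[0].upper()
        i = 1
        while i < len(t) and t[i].isdigit():
            i += 1
        if i == 1 or i == len(t):
            raise ValueError(f"cannot parse variant {text!r}")
        pos = int(t[1:i])
        rest = t[i:]
        if rest.lower() in ("del", "delete", "deletion"):
            sub = DELETION
        elif len(rest) == 1 and rest.upper() in AA_ONE_TO_THREE:
            sub = AA_ONE_TO_THREE[rest.upper()]
        elif rest.upper() in STANDARD_AA:
            sub = rest.upper()
        else:
            raise ValueError(f"cannot parse substitution in {text!r}")
        if wt1 not in AA_ONE_TO_THREE:
            raise ValueError(f"unknown wild-type code in {text!r}")
        return cls(position=pos, wild_type=AA_ONE_TO_THREE[wt1], substitution=sub)

    def __str__(self) -> str:
        from .residues import AA_THREE_TO_ONE

        sub = "del" if self.is_deletion else AA_THREE_TO_ONE[self.substitution]
        return f"{AA_THREE_TO_ONE[self.wild_type]}{self.position}{sub}"


# --- enumeration -----------------------------------------------------------

def _chi1_wells_for_bin(phi_bin: float, psi_bin: float) -> set[float]:
    """Coarse backbone-dependent map: which chi1 wells a phi/psi bin allows.

    Helical backbones exclude the g+ (+60) well (it collides with the
    preceding turn); positive-phi backbones exclude g- (-60). Extended
    backbones allow all three staggered wells.
    """
    if phi_bin >= 0:
        return {60.0, 180.0}
    if -120.0 <= psi_bin < 50.0:  # helical region
        return {-60.0, 180.0}
    return {-60.0, 60.0, 180.0}  # extended / PPII


def enumerate_rotamers(
    amino_acid: str,
    library: RotamerLibrary | None = None,
    backbone_phi_psi: tuple[float, float] | None = None,
) -> list[Rotamer]:
    """Candidate rotamers for an amino acid from a library.

    With a backbone-dependent library the residue's (phi, psi) must be
    given; entries are filtered to the chi1 wells allowed by the coarse
    phi/psi bin. Gly and Ala return the single trivial rotamer.
    """
    aa = amino_acid.upper()
    if aa not in STANDARD_AA:
        raise ValueError(f"not a standard amino acid: {amino_acid!r}")
    if library is None:
        library = load_default_library()
    entries = library.entries[aa]
    if not library.backbone_dependent:
        return list(entries)
    if backbone_phi_psi is None:
        raise ValueError("backbone-dependent library requires backbone_phi_psi")
    step = library.phi_psi_bin_deg
    phi_bin = np.floor(backbone_phi_psi[0] / step) * step
    psi_bin = np.floor(backbone_phi_psi[1] / step) * step
    wells = _chi1_wells_for_bin(phi_bin, psi_bin)
    out = []
    for rot in entries:
        if not rot.chi.values:
            out.append(rot)
            continue
        chi1 = rot.chi.values[0]
        if any(abs(wrap_angle(chi1 - w)) <= 40.0 for w in wells):
            out.append(rot)
    return out or list(entries)


def grid_rotamers(amino_acid: str, step: float | list[float] = 30.0) -> list[Rotamer]:
    """Exhaustive chi-grid enumeration: the Cartesian product of a uniform
    grid over each chi. ``step`` may be one step for all chis or one per chi;
    each chi gets exactly ``360 / step`` points starting at -180 + step."""
    aa = amino_acid.upper()
    n = chi_count(aa)
    if n == 0:
        return [Rotamer(aa, ChiAngles((), aa), source="grid", label="-")]
    if np.isscalar(step):
        steps = [float(step)] * n
    else:
        steps = [float(s) for s in step]
        if len(steps) != n:
            raise ValueError(f"{aa} needs {n} grid steps, got {len(steps)}")
    axes = []
    for s in steps:
        count = int(round(360.0 / s))
        if count < 1 or abs(count * s - 360.0) > 1e-6:
            raise ValueError(f"grid step {s} does not divide 360")
        axes.append([wrap_angle(-180.0 + s * (k + 1)) for k in range(count)])
    out = []
    for combo in itertools.product(*axes):
        out.append(
            Rotamer(
                aa,
                ChiAngles(tuple(combo), aa),
                source="grid",
                label="/".join(f"{c:.0f}" for c in combo),
            )
        )
    return out


# --- construction ----------------------------------------------------------

def _element_of(atom_name: str) -> str:
    # side-chain heavy atom names start with their element letter
    return "S" if atom_name.startswith("S") else atom_name[0]


def build_side_chain(
    backbone: Residue,
    target: str,
    rotamer: Rotamer,
    geometry: dict | None = None,
    radius_table: dict[str, float] | None = None,
) -> list[Atom]:
    """Build the heavy side-chain atoms (CB onwards) of ``target`` on the
    residue's backbone at the rotamer's chi angles.

    CB is placed from N/CA/C with ideal tetrahedral L-amino-acid geometry;
    subsequent atoms follow the per-amino-acid internal-coordinate recipe.
    Gly builds nothing, Ala builds CB only.
    """
    aa = target.upper()
    if aa not in STANDARD_AA:
        raise ValueError(f"not a standard amino acid: {target!r}")
    if rotamer.amino_acid != aa:
        raise ValueError(f"rotamer is for {rotamer.amino_acid}, target is {aa}")
    recipes = SIDECHAIN_RECIPES if geometry is None else geometry.get("recipes", SIDECHAIN_RECIPES)
    cb_spec = CB_PLACEMENT if geometry is None else geometry.get("cb", CB_PLACEMENT)
    if aa not in recipes:
        raise KeyError(f"geometry table has no recipe for {aa}")
    radii = DEFAULT_VDW_RADII if radius_table is None else radius_table
    for name in ("N", "CA", "C"):
        if not backbone.has_atom(name):
            raise ValueError(
                f"residue {backbone.amino_acid}{backbone.number} lacks backbone atom {name}"
            )
    if aa == "GLY":
        return []
    pos: dict[str, np.ndarray] = {
        n: backbone.atom(n).position for n in ("N", "CA", "C")
    }
    a, b, c = cb_spec["refs"]
    pos["CB"] = place_atom(
        pos[a], pos[b], pos[c], cb_spec["length"], cb_spec["angle"], cb_spec["torsion"]
    )
    built = [("CB", pos["CB"])]
    chi = rotamer.chi.values
    for entry in recipes[aa]:
        name, refs, length, angle, torsion = entry
        if isinstance(torsion, (tuple, list)) and torsion[0] == "chi":
            k = int(torsion[1])
            offset = float(torsion[2]) if len(torsion) > 2 else 0.0
            tor = wrap_angle(chi[k - 1] + offset)
        else:
            tor = float(torsion)
        pa, pb, pc = (pos[r] for r in refs)
        pos[name] = place_atom(pa, pb, pc, length, angle, tor)
        built.append((name, pos[name]))
    atoms = []
    for name, p in built:
        elem = _element_of(name)
        atoms.append(
            Atom(
                name=name,
                element=elem,
                position=p,
                vdw_radius=radii[elem],
            )
        )
    return atoms


def replace_residue(
    protomer: Protomer,
    variant: VariantSpec,
    rotamer: Rotamer,
    geometry: dict | None = None,
) -> Protomer:
    """Return a copy of the protomer with the variant side chain built in
    place of the wild-type one; backbone coordinates are untouched."""
    if variant.is_deletion:
        raise ValueError(
            "deletions are not modelled geometrically; use the classifier's "
            "rule-based path"
        )
    template = protomer.residue(variant.position)
    if template.amino_acid != variant.wild_type:
        raise ValueError(
            f"template residue {variant.position} is {template.amino_acid}, "
            f"variant expects wild type {variant.wild_type}"
        )
    new_side = build_side_chain(template, variant.substitution, rotamer, geometry)
    out = protomer.copy()
    res = out.residue(variant.position)
    backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    res.amino_acid = variant.substitution
    res.atoms = backbone + new_side
    return out
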