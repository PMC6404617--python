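"""Synthetic, fully controlled structures and count tables.

Every stage of the pipeline is testable without downloads: a toy
two-strand "mini hairpin" emulates the loop-packing site where a long
glutamate side chain seals a groove (so Glu->Val clashes and Glu->Gly
loses contacts, by construction); a synthetic protomer ensemble carries a
lysine donor whose hydrogen-bond partner is assigned per an explicit
partition; and a binomial sampler emulates the inclusion-count assay.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch_superpose, place_atom
from .residues import DEFAULT_VDW_RADII
from .rotamers import ChiAngles, Rotamer, build_side_chain
from .structure import Atom, Protomer, Residue, Structure, assign_vdw_radii
from .aggregation import InclusionCounts

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "build_strand",
    "make_mini_hairpin",
    "make_ensemble",
    "make_counts_table",
    "HAIRPIN_GLU_POSITION",
    "ENSEMBLE_DONOR",
    "ENSEMBLE_ACCEPTORS",
]

# residue numbering conventions of the generated fixtures
HAIRPIN_GLU_POSITION = 4
ENSEMBLE_DONOR = (2, "NZ")  # lysine donor in the ensemble scaffold
ENSEMBLE_ACCEPTORS = (10, 20)  # Asp-like and Glu-like acceptor residues

_BETA_PHI, _BETA_PSI = -139.0, 135.0


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind + kind-specific parameters."""

    kind: str  # mini_hairpin | ensemble | counts_table
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    makers = {
        "mini_hairpin": make_mini_hairpin,
        "ensemble": make_ensemble,
        "counts_table": make_counts_table,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return makers[spec.kind](seed=spec.seed, **spec.parameters)


def _atom(name: str, pos, element: str | None = None) -> Atom:
    elem = element or ("S" if name.startswith("S") else name[0])
    return Atom(name=name, element=elem, position=np.asarray(pos, float),
                vdw_radius=DEFAULT_VDW_RADII.get(elem))


def build_strand(
    sequence: list[str],
    start_number: int = 1,
    phi: float = _BETA_PHI,
    psi: float = _BETA_PSI,
) -> list[Residue]:
    """Extended peptide backbone with ideal bond geometry at uniform
    (phi, psi); residues get CB (and nothing further) unless Gly."""
    n_res = len(sequence)
    # seed the first three backbone atoms explicitly
    coords: list[dict[str, np.ndarray]] = [{} for _ in range(n_res)]
    coords[0]["N"] = np.array([0.0, 0.0, 0.0])
    coords[0]["CA"] = np.array([1.46, 0.0, 0.0])
    coords[0]["C"] = coords[0]["CA"] + 1.52 * np.array(
        [np.cos(np.radians(180 - 111.0)), np.sin(np.radians(180 - 111.0)), 0.0]
    )
    for i in range(n_res):
        ri = coords[i]
        if i > 0:
            prev = coords[i - 1]
            ri["N"] = place_atom(prev["N"], prev["CA"], prev["C"], 1.33, 116.2, psi)
            ri["CA"] = place_atom(prev["CA"], prev["C"], ri["N"], 1.46, 121.7, 180.0)
            ri["C"] = place_atom(prev["C"], ri["N"], ri["CA"], 1.52, 111.0, phi)
        if i + 1 < n_res:
            # O placed after the next N exists (trans peptide plane)
            pass
    for i in range(n_res):
        ri = coords[i]
        if i + 1 < n_res:
            nxt_n = coords[i + 1]["N"]
            # O is anti to the next N across the C=O plane
            ri["O"] = place_atom(nxt_n, ri["CA"], ri["C"], 1.23, 120.8, 180.0)
        else:
            ri["O"] = place_atom(ri["N"], ri["CA"], ri["C"], 1.23, 120.8, psi + 180.0)
    residues = []
    for i, aa in enumerate(sequence):
        aa = aa.upper()
        atoms = [_atom(n, coords[i][n]) for n in ("N", "CA", "C", "O")]
        res = Residue(number=start_number + i, amino_acid=aa, atoms=atoms)
        if aa != "GLY":
            # CB only; callers install full side chains where needed
            res.atoms.extend(
                build_side_chain(res, "ALA", Rotamer("ALA", ChiAngles((), "ALA")))
            )
        residues.append(res)
    return residues


def _rigid(rng: np.random.Generator, max_shift: float = 20.0):
    """Random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return rot, shift


def _apply_rigid(residues: list[Residue], rot: np.ndarray, shift: np.ndarray):
    for res in residues:
        for atom in res.atoms:
            atom.position = rot @ atom.position + shift


# --- mini hairpin ----------------------------------------------------------

def make_mini_hairpin(
    seed: int = 0,
    separation: float = 0.0,
    glu_chi: tuple[float, float, float] = (-60.0, -60.0, 0.0),
    lys_chi: tuple[float, float, float, float] = (180.0, 180.0, 180.0, 180.0),
    height: float = 8.5,
    shift: float = 1.5,
    offset: float = 2.0,
    strand_length: int = 7,
) -> Structure:
    """Two antiparallel strands whose packing pivots on a central Glu.

    Strand A (residues 1..7, Ala with a central Glu) faces strand B
    (residues 101..107, Ala with a central Lys whose side chain descends
    toward the Glu site, the way a lysine packs against a glutamate at a
    loop-loop interface). The placement is chosen so that, by
    construction: the Glu at ``glu_chi`` packs against the descending
    lysine at van der Waals contact (no clash) distance; every Val chi1
    rotamer at the Glu site clashes with the lysine chain; and Gly strips
    the contacts. ``separation`` moves strand B away along the packing
    axis (about +2 A relieves the Val clashes).

    Deterministic; ``seed`` is accepted for interface uniformity only.
    """
    seq_a = ["ALA"] * strand_length
    seq_a[HAIRPIN_GLU_POSITION - 1] = "GLU"
    strand_a = build_strand(seq_a, start_number=1)
    glu = strand_a[HAIRPIN_GLU_POSITION - 1]
    # replace the placeholder CB with the full Glu side chain
    glu.atoms = [a for a in glu.atoms if a.name in ("N", "CA", "C", "O")]
    rot = Rotamer("GLU", ChiAngles(tuple(glu_chi), "GLU"))
    glu.atoms.extend(build_side_chain(glu, "GLU", rot))

    strand_b = build_strand(["ALA"] * strand_length, start_number=101)

    # local frame at the Glu: e1 strand direction, e2 side-chain (packing)
    # direction, e3 the sheet-plane normal
    ca_first = strand_a[0].atom("CA").position
    ca_last = strand_a[-1].atom("CA").position
    e1 = ca_last - ca_first
    e1 /= np.linalg.norm(e1)
    cb = glu.atom("CB").position
    ca = glu.atom("CA").position
    e2 = cb - ca
    e2 -= e1 * np.dot(e2, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)

    # rotate strand B 180 degrees about e2 (antiparallel) and park it
    # above the Glu along e2, with register and lateral offsets
    rot180 = 2.0 * np.outer(e2, e2) - np.eye(3)
    b_center = 0.5 * (
        strand_b[0].atom("CA").position + strand_b[-1].atom("CA").position
    )
    target_center = (
        ca + (height + separation) * e2 + shift * e1 + offset * e3
    )
    for res in strand_b:
        for atom in res.atoms:
            atom.position = rot180 @ (atom.position - b_center) + target_center

    # the knob: the central-most B residue whose CB points back toward the
    # Glu site becomes a lysine with a descending side chain
    knob = max(
        strand_b[1:-1],
        key=lambda r: -float(
            np.dot(r.atom("CB").position - r.atom("CA").position, e2)
        ),
    )
    knob.atoms = [a for a in knob.atoms if a.name in ("N", "CA", "C", "O")]
    knob.amino_acid = "LYS"
    knob.atoms.extend(
        build_side_chain(knob, "LYS", Rotamer("LYS", ChiAngles(tuple(lys_chi), "LYS")))
    )

    protomer = Protomer(chain_id="F", residues=strand_a + strand_b,
                        source=f"mini_hairpin/seed{seed}")
    structure = Structure(accession="mini_hairpin", protomers=[protomer])
    return assign_vdw_radii(structure, DEFAULT_VDW_RADII)


# --- conformer ensemble ----------------------------------------------------

def _place_acceptor(aa: str, acceptor_atom: str, target: np.ndarray,
                    direction: np.ndarray, number: int) -> Residue:
    """Build a standalone acceptor residue and rigidly park it so its
    acceptor oxygen sits at ``target`` with the rest of the residue
    receding along ``direction``."""
    res = Residue(number=number, amino_acid=aa,
                  atoms=[_atom("N", (0.0, 1.4, 0.0)),
                         _atom("CA", (0.0, 0.0, 0.0)),
                         _atom("C", (1.4, -0.6, 0.0)),
                         _atom("O", (2.5, 0.0, 0.1))])
    chi = {"ASP": (-60.0, 0.0), "GLU": (-60.0, 180.0, 0.0)}[aa]
    res.atoms.extend(build_side_chain(res, aa, Rotamer(aa, ChiAngles(chi, aa))))
    ante_name = {"ASP": "CG", "GLU": "CD"}[aa]
    o = res.atom(acceptor_atom).position
    v = o - res.atom(ante_name).position
    v /= np.linalg.norm(v)
    d = direction / np.linalg.norm(direction)
    # rotation taking v to d (Rodrigues)
    c = float(np.dot(v, d))
    if c < -0.999999:
        rot = -np.eye(3)
    else:
        k = np.cross(v, d)
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + kx + kx @ kx / (1.0 + c)
    for atom in res.atoms:
        atom.position = rot @ (atom.position - o) + target
    return res


def make_ensemble(
    n: int = 36,
    partition: dict[str, int] | None = None,
    seed: int = 0,
    chi_noise_deg: float = 4.0,
    rigid_motions: bool = True,
) -> list[Protomer]:
    """N copies of a lysine-donor scaffold whose hydrogen-bond partner
    follows an explicit partition.

    ``partition`` maps {"A": k1, "B": k2, "none": k3} (summing to n) onto
    the Asp-like acceptor (residue 10), the Glu-like acceptor (residue 20)
    and the no-bond conformer. Each copy gets its own rigid motion and a
    small chi perturbation inside the assigned conformer well.
    """
    if partition is None:
        if n == 36:
            partition = {"A": 5, "none": 23, "B": 8}
        else:  # same three states, roughly proportional
            a = max(1, round(5 * n / 36))
            b = max(1, round(8 * n / 36))
            partition = {"A": a, "B": b, "none": n - a - b}
    partition = dict(partition)
    if sum(partition.values()) != n:
        raise ValueError(
            f"partition {partition} does not sum to ensemble size {n}"
        )
    unknown = set(partition) - {"A", "B", "none"}
    if unknown:
        raise ValueError(f"unknown partition keys: {sorted(unknown)}")

    scaffold = build_strand(["ALA", "LYS", "ALA"], start_number=1)
    lys = scaffold[1]
    lys.atoms = [a for a in lys.atoms if a.name in ("N", "CA", "C", "O")]
    chi_by_state = {
        "A": (-60.0, 180.0, 180.0, 180.0),
        "B": (180.0, 180.0, 180.0, 180.0),
        "none": (60.0, -60.0, 60.0, 180.0),
    }

    def lys_with_chi(chi) -> list[Atom]:
        return build_side_chain(lys, "LYS", Rotamer("LYS", ChiAngles(tuple(chi), "LYS")))

    # park one acceptor at the A-state NZ and one at the B-state NZ
    acceptors = {}
    for state, resnum, aa, oname in (
        ("A", ENSEMBLE_ACCEPTORS[0], "ASP", "OD1"),
        ("B", ENSEMBLE_ACCEPTORS[1], "GLU", "OE1"),
    ):
        side = lys_with_chi(chi_by_state[state])
        nz = next(a.position for a in side if a.name == "NZ")
        ce = next(a.position for a in side if a.name == "CE")
        u = nz - ce
        u /= np.linalg.norm(u)
        acceptors[state] = _place_acceptor(aa, oname, nz + 2.85 * u, u, resnum)

    rng = np.random.default_rng(seed)
    states = (["A"] * partition.get("A", 0)
              + ["none"] * partition.get("none", 0)
              + ["B"] * partition.get("B", 0))
    protomers = []
    for k, state in enumerate(states):
        residues = [r.copy() for r in scaffold]
        residues.extend([acceptors["A"].copy(), acceptors["B"].copy()])
        lys_copy = residues[1]
        chi = np.array(chi_by_state[state], float)
        if chi_noise_deg > 0:
            chi = chi + rng.uniform(-chi_noise_deg, chi_noise_deg, size=4)
        lys_copy.atoms = [a for a in lys_copy.atoms if a.name in ("N", "CA", "C", "O")]
        lys_copy.atoms.extend(
            build_side_chain(lys_copy, "LYS", Rotamer("LYS", ChiAngles(tuple(chi), "LYS")))
        )
        if rigid_motions:
            rot, shift = _rigid(rng)
            _apply_rigid(residues, rot, shift)
        protomers.append(
            Protomer(chain_id="E", residues=residues,
                     source=f"ensemble/seed{seed}/copy{k}/{state}")
        )
    return protomers


# --- count tables ----------------------------------------------------------

def make_counts_table(
    probabilities: dict[str, float] | None = None,
    n_cells: dict[str, int] | int = 250,
    timepoints: tuple[int, ...] = (24, 48),
    seed: int = 0,
) -> list[InclusionCounts]:
    """Binomial emulation of the inclusion assay: per variant and
    timepoint, draw inclusions ~ Binomial(n_cells, p)."""
    probabilities = probabilities or {"WT": 0.008, "MUTANT": 0.25}
    rng = np.random.default_rng(seed)
    out = []
    for variant, p in probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{variant}: probability {p} outside [0, 1]")
        for tp in timepoints:
            ncells = n_cells[variant] if isinstance(n_cells, dict) else int(n_cells)
            out.append(
                InclusionCounts(
                    variant=variant,
                    timepoint=tp,
                    n_counted=ncells,
                    n_inclusions=int(rng.binomial(ncells, p)),
                )
            )
    return out
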