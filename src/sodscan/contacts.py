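"""Geometric scoring of a placed side chain against its environment.

Three pair categories are distinguished, priority-ordered
clash > hydrogen bond > van der Waals contact:

* steric clash      -- r_i + r_j - d > overlap threshold (default 0.4 A)
* hydrogen bond     -- donor-acceptor distance and antecedent angle criteria
* van der Waals     -- r_i + r_j - clash_threshold < d <= r_i + r_j + shell

Covalently related pairs (1-2, 1-3, 1-4) within the probe residue and
across its own peptide links are excluded; pairs between different
residues are never excluded. Neighbour search uses a KD-tree; tests check
it against brute-force all-pairs enumeration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import bond_angle
from .residues import (
    BACKBONE_ACCEPTOR,
    BACKBONE_DONOR,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    residue_bonds,
)
from .rotamers import Rotamer, VariantSpec, build_side_chain
from .structure import Atom, Protomer, Residue

__all__ = [
    "HbondCriteria",
    "ScanParams",
    "ContactReport",
    "detect_clashes",
    "count_vdw_contacts",
    "detect_hbonds",
    "residue_donors",
    "residue_acceptors",
    "score_rotamer",
    "environment_residues",
]


@dataclass(frozen=True)
class HbondCriteria:
    """Geometric hydrogen-bond definition.

    In heavy-atom mode (crystal structures without hydrogens) a bond
    requires donor-acceptor distance <= max_donor_acceptor_distance and
    antecedent-donor-acceptor angle >= min_angle.
    """

    max_donor_acceptor_distance: float = 3.5
    min_angle: float = 90.0
    hydrogen_aware: bool = False

    def __post_init__(self):
        if not (0.0 < self.max_donor_acceptor_distance <= 5.0):
            raise ValueError("max_donor_acceptor_distance must be in (0, 5] A")
        if not (0.0 <= self.min_angle <= 180.0):
            raise ValueError("min_angle must be in [0, 180] degrees")


@dataclass(frozen=True)
class ScanParams:
    """Tunable thresholds of the scanning pipeline, echoed into reports."""

    clash_overlap: float = 0.4  # A of vdW overlap that counts as a clash
    contact_shell: float = 0.5  # A beyond the radius sum still counted as contact
    environment_radius: float = 8.0  # A around the mutated residue's CB
    hbond: HbondCriteria = field(default_factory=HbondCriteria)
    f_contact: float = 0.6  # fraction of wild-type contacts a variant must keep
    # STERIC_CLASH when the variant's clash-free rotamer fraction is below
    # this multiple of the wild-type amino acid's own clash-free fraction
    clash_free_fraction: float = 0.5
    rotamer_mode: str = "library"  # "library" or "grid"
    grid_step: float = 30.0

    def as_dict(self) -> dict:
        return {
            "clash_overlap": self.clash_overlap,
            "contact_shell": self.contact_shell,
            "environment_radius": self.environment_radius,
            "hbond_max_distance": self.hbond.max_donor_acceptor_distance,
            "hbond_min_angle": self.hbond.min_angle,
            "f_contact": self.f_contact,
            "clash_free_fraction": self.clash_free_fraction,
            "rotamer_mode": self.rotamer_mode,
            "grid_step": self.grid_step,
        }


@dataclass
class ContactReport:
    """Clashes, van der Waals contacts and hydrogen bonds of a probe atom
    set against an environment."""

    clashes: list[tuple[str, str, float, float]] = field(default_factory=list)
    vdw_contacts: list[tuple[str, str, float]] = field(default_factory=list)
    hbonds: list[tuple[str, str, float, float]] = field(default_factory=list)
    environment: list[int] = field(default_factory=list)

    @property
    def n_clashes(self) -> int:
        return len(self.clashes)

    @property
    def n_contacts(self) -> int:
        return len(self.vdw_contacts)

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)

    @property
    def worst_overlap(self) -> float:
        return max((c[3] for c in self.clashes), default=0.0)


def _require_radii(atoms: list[Atom], where: str):
    for a in atoms:
        if a.is_hydrogen:
            continue
        if a.vdw_radius is None or a.vdw_radius <= 0:
            raise ValueError(f"{where}: atom {a.name} has no van der Waals radius")


def _candidate_pairs(probe: list[Atom], environment: list[Atom], reach: float):
    """(i, j, d) for all probe/environment pairs with d <= reach."""
    if not probe or not environment:
        return
    env_xyz = np.array([a.position for a in environment])
    tree = cKDTree(env_xyz)
    for i, pa in enumerate(probe):
        for j in tree.query_ball_point(pa.position, reach):
            d = float(np.linalg.norm(pa.position - env_xyz[j]))
            yield i, j, d


def detect_clashes(
    probe: list[Atom],
    environment: list[Atom],
    overlap_threshold: float = 0.4,
    exclusions: set[tuple[int, int]] = frozenset(),
) -> list[tuple[int, int, float, float]]:
    """Steric clashes between probe and environment heavy atoms.

    Returns (probe_index, env_index, distance, overlap) for every
    non-excluded pair with overlap = r_i + r_j - d > overlap_threshold.
    """
    probe = [a for a in probe if not a.is_hydrogen]
    environment = [a for a in environment if not a.is_hydrogen]
    _require_radii(probe, "probe")
    _require_radii(environment, "environment")
    if not probe or not environment:
        return []
    max_sum = max(a.vdw_radius for a in probe) + max(a.vdw_radius for a in environment)
    out = []
    for i, j, d in _candidate_pairs(probe, environment, max_sum):
        if (i, j) in exclusions:
            continue
        overlap = probe[i].vdw_radius + environment[j].vdw_radius - d
        if overlap > overlap_threshold:
            out.append((i, j, d, overlap))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def count_vdw_contacts(
    probe: list[Atom],
    environment: list[Atom],
    shell: float = 0.5,
    clash_threshold: float = 0.4,
    exclusions: set[tuple[int, int]] = frozenset(),
) -> list[tuple[int, int, float]]:
    """Favourable van der Waals contacts: pairs with
    r_i + r_j - clash_threshold < d <= r_i + r_j + shell."""
    probe = [a for a in probe if not a.is_hydrogen]
    environment = [a for a in environment if not a.is_hydrogen]
    _require_radii(probe, "probe")
    _require_radii(environment, "environment")
    if not probe or not environment:
        return []
    max_sum = max(a.vdw_radius for a in probe) + max(a.vdw_radius for a in environment)
    out = []
    for i, j, d in _candidate_pairs(probe, environment, max_sum + shell):
        if (i, j) in exclusions:
            continue
        rsum = probe[i].vdw_radius + environment[j].vdw_radius
        if rsum - clash_threshold < d <= rsum + shell:
            out.append((i, j, d))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


# --- hydrogen bonds --------------------------------------------------------

def residue_donors(residue: Residue, include_backbone: bool = True):
    """(label, donor_atom, antecedent_atom) triples for a residue."""
    out = []
    specs = []
    if include_backbone:
        specs.append(BACKBONE_DONOR)
    specs.extend(SIDECHAIN_DONORS.get(residue.amino_acid, []))
    for name, ante in specs:
        if residue.has_atom(name) and residue.has_atom(ante):
            out.append(
                (f"{residue.amino_acid}{residue.number}:{name}",
                 residue.atom(name), residue.atom(ante))
            )
    return out


def residue_acceptors(residue: Residue, include_backbone: bool = True):
    out = []
    specs = []
    if include_backbone:
        specs.append(BACKBONE_ACCEPTOR)
    specs.extend(SIDECHAIN_ACCEPTORS.get(residue.amino_acid, []))
    for name, ante in specs:
        if residue.has_atom(name) and residue.has_atom(ante):
            out.append(
                (f"{residue.amino_acid}{residue.number}:{name}",
                 residue.atom(name), residue.atom(ante))
            )
    return out


def hbond_geometry_ok(
    donor: Atom, donor_antecedent: Atom, acceptor: Atom, criteria: HbondCriteria
) -> tuple[bool, float, float]:
    """Check one donor/acceptor pair; returns (ok, distance, angle)."""
    d = float(np.linalg.norm(donor.position - acceptor.position))
    if d < 1e-6 or d > criteria.max_donor_acceptor_distance:
        return False, d, float("nan")
    ang = bond_angle(donor_antecedent.position, donor.position, acceptor.position)
    return ang >= criteria.min_angle, d, ang


def detect_hbonds(
    donors: list[tuple[str, Atom, Atom]],
    acceptors: list[tuple[str, Atom, Atom]],
    criteria: HbondCriteria | None = None,
) -> list[tuple[str, str, float, float]]:
    """All donor->acceptor pairs satisfying the geometric criteria.

    Donors and acceptors are (label, atom, antecedent) triples as produced
    by residue_donors / residue_acceptors.
    """
    criteria = criteria or HbondCriteria()
    out = []
    for dlab, datom, dante in donors:
        for alab, aatom, _ante in acceptors:
            if datom is aatom:
                continue
            ok, dist, ang = hbond_geometry_ok(datom, dante, aatom, criteria)
            if ok:
                out.append((dlab, alab, dist, ang))
    return out


# --- probe-in-environment scoring -----------------------------------------

def _bond_graph(aa: str, prev_aa: str | None, next_aa: str | None) -> dict:
    """Atom-name adjacency for one residue plus its peptide neighbours.

    Nodes are (slot, name) with slot in {-1, 0, +1}."""
    adj: dict[tuple[int, str], set] = {}

    def add(u, v):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    for slot, res_aa in ((-1, prev_aa), (0, aa), (1, next_aa)):
        if res_aa is None:
            continue
        for u, v in residue_bonds(res_aa):
            add((slot, u), (slot, v))
    if prev_aa is not None:
        add((-1, "C"), (0, "N"))
    if next_aa is not None:
        add((0, "C"), (1, "N"))
    return adj


def _graph_distances(adj: dict, start, max_depth: int = 4) -> dict:
    dist = {start: 0}
    q = deque([start])
    while q:
        u = q.popleft()
        if dist[u] >= max_depth:
            continue
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def environment_residues(
    protomer: Protomer, position: int, radius: float = 8.0
) -> list[Residue]:
    """Residues with any heavy atom within ``radius`` of the anchor point
    (CB, or CA for Gly) of the residue at ``position``."""
    target = protomer.residue(position)
    anchor_name = "CB" if target.has_atom("CB") else "CA"
    anchor = target.atom(anchor_name).position
    out = []
    for res in protomer.residues:
        coords = np.array([a.position for a in res.atoms if not a.is_hydrogen])
        if coords.size and np.min(np.linalg.norm(coords - anchor, axis=1)) <= radius:
            out.append(res)
    return out


def _probe_report(
    probe: list[Atom],
    probe_aa: str,
    target: Residue,
    env_res: list[Residue],
    protomer: Protomer,
    params: ScanParams,
) -> ContactReport:
    """Score a probe side chain (built or wild type) in its environment."""
    env_atoms: list[Atom] = []
    env_labels: list[str] = []
    env_keys: list[tuple[int, str] | None] = []  # bond-graph node when relevant
    idx = protomer.residues.index(target)
    prev_res = protomer.residues[idx - 1] if idx > 0 else None
    next_res = protomer.residues[idx + 1] if idx + 1 < len(protomer.residues) else None
    # only direct chain neighbours take part in covalent exclusions
    if prev_res is not None and prev_res.number != target.number - 1:
        prev_res = None
    if next_res is not None and next_res.number != target.number + 1:
        next_res = None

    for res in env_res:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            if res is target:
                # the target's own side chain is what the probe replaces;
                # only its backbone stays in the environment
                if atom.name not in ("N", "CA", "C", "O", "OXT"):
                    continue
                slot = 0
            elif prev_res is not None and res is prev_res:
                slot = -1
            elif next_res is not None and res is next_res:
                slot = 1
            else:
                slot = None
            env_atoms.append(atom)
            env_labels.append(f"{res.amino_acid}{res.number}:{atom.name}")
            env_keys.append((slot, atom.name) if slot is not None else None)

    adj = _bond_graph(
        probe_aa,
        prev_res.amino_acid if prev_res is not None else None,
        next_res.amino_acid if next_res is not None else None,
    )
    exclusions: set[tuple[int, int]] = set()
    for i, pa in enumerate(probe):
        dist = _graph_distances(adj, (0, pa.name), max_depth=3)
        for j, key in enumerate(env_keys):
            if key is not None and key in dist:
                exclusions.add((i, j))

    report = ContactReport(environment=[r.number for r in env_res])
    clash = detect_clashes(probe, env_atoms, params.clash_overlap, exclusions)
    clash_pairs = {(i, j) for i, j, _, _ in clash}
    contacts = count_vdw_contacts(
        probe, env_atoms, params.contact_shell, params.clash_overlap, exclusions
    )

    # hydrogen bonds: probe side chain in both roles against environment chemistry
    probe_res = Residue(number=target.number, amino_acid=probe_aa,
                        atoms=[target.atom(n) for n in ("N", "CA", "C", "O")
                               if target.has_atom(n)] + list(probe))
    pdon = residue_donors(probe_res, include_backbone=False)
    pacc = residue_acceptors(probe_res, include_backbone=False)
    env_don, env_acc = [], []
    for res in env_res:
        if res is target:
            continue
        env_don.extend(residue_donors(res))
        env_acc.extend(residue_acceptors(res))
    hb = detect_hbonds(pdon, env_acc, params.hbond)
    hb += [(d, a, dist, ang) for d, a, dist, ang in detect_hbonds(env_don, pacc, params.hbond)]
    hb_atom_pairs = set()
    # map H-bond pairs back to (probe_index, env_index) to enforce category priority
    probe_index = {a.name: i for i, a in enumerate(probe)}
    env_index: dict[str, int] = {lab: j for j, lab in enumerate(env_labels)}
    kept_hb = []
    for dlab, alab, dist, ang in hb:
        pname = dlab.split(":")[-1] if dlab.split(":")[-1] in probe_index else alab.split(":")[-1]
        elab = alab if alab in env_index else dlab
        pair = (probe_index.get(pname), env_index.get(elab))
        if pair[0] is None or pair[1] is None:
            kept_hb.append((dlab, alab, dist, ang))
            continue
        if pair in clash_pairs:
            continue  # clash takes priority
        hb_atom_pairs.add(pair)
        kept_hb.append((dlab, alab, dist, ang))

    probe_label = lambda i: probe[i].name  # noqa: E731
    for i, j, d, ov in clash:
        report.clashes.append((probe_label(i), env_labels[j], round(d, 3), round(ov, 3)))
    for i, j, d in contacts:
        if (i, j) in clash_pairs or (i, j) in hb_atom_pairs:
            continue
        report.vdw_contacts.append((probe_label(i), env_labels[j], round(d, 3)))
    report.hbonds = [(d, a, round(dist, 3), round(ang, 1)) for d, a, dist, ang in kept_hb]
    return report


def score_rotamer(
    protomer: Protomer,
    variant: VariantSpec,
    rotamer: Rotamer,
    params: ScanParams | None = None,
) -> tuple[ContactReport, ContactReport]:
    """Build the variant side chain at one rotamer and score it.

    Returns (variant_report, wild_type_report); the wild-type report scores
    the template's own side chain in the same environment so callers can
    difference contact and H-bond counts.
    """
    params = params or ScanParams()
    if variant.is_deletion:
        raise ValueError("deletions have no rotamers to score")
    target = protomer.residue(variant.position)
    if target.amino_acid != variant.wild_type:
        raise ValueError(
            f"template residue {variant.position} is {target.amino_acid}, "
            f"expected {variant.wild_type}"
        )
    env = environment_residues(protomer, variant.position, params.environment_radius)
    probe = build_side_chain(target, variant.substitution, rotamer)
    var_report = _probe_report(probe, variant.substitution, target, env, protomer, params)
    wt_probe = target.side_chain_atoms()
    wt_report = _probe_report(wt_probe, target.amino_acid, target, env, protomer, params)
    return var_report, wt_report
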