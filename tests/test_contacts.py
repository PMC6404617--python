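"""Clash, van der Waals contact and hydrogen-bond detection against
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_clashes, brute_contacts, brute_hbonds, random_atoms

from sodscan.contacts import (
    HbondCriteria,
    ScanParams,
    count_vdw_contacts,
    detect_clashes,
    detect_hbonds,
    residue_acceptors,
    residue_donors,
    score_rotamer,
)
from sodscan.fixtures import build_strand, make_mini_hairpin
from sodscan.rotamers import ChiAngles, Rotamer, VariantSpec, build_side_chain
from sodscan.structure import Atom, Residue
from sodscan.superpose import measure_chi


def carbon(x, y=0.0, z=0.0):
    return Atom(name="C", element="C", position=(x, y, z), vdw_radius=1.70)


class TestClashArithmetic:
    def test_two_carbons_at_3p5_do_not_clash(self):
        assert detect_clashes([carbon(0)], [carbon(3.5)], 0.4) == []

    def test_two_carbons_at_2p9_clash_with_overlap_0p5(self):
        clashes = detect_clashes([carbon(0)], [carbon(2.9)], 0.4)
        assert len(clashes) == 1
        assert clashes[0][3] == pytest.approx(0.5, abs=1e-12)

    def test_missing_radius_is_error(self):
        bare = Atom(name="C", element="C", position=(0, 0, 0))
        with pytest.raises(ValueError, match="radius"):
            detect_clashes([bare], [carbon(3.0)], 0.4)

    def test_exclusions_respected(self):
        probe, env = [carbon(0)], [carbon(2.0)]
        assert detect_clashes(probe, env, 0.4, exclusions={(0, 0)}) == []


class TestContactArithmetic:
    def test_contact_inside_shell(self):
        assert len(count_vdw_contacts([carbon(0)], [carbon(3.6)], shell=0.5)) == 1

    def test_no_contact_beyond_shell(self):
        assert count_vdw_contacts([carbon(0)], [carbon(4.2)], shell=0.5) == []

    def test_clash_pair_not_a_contact(self):
        assert count_vdw_contacts([carbon(0)], [carbon(2.5)], shell=0.5) == []


class TestOracleEquivalence:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_clash_and_contact_sets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        probe = random_atoms(rng, 12, box=8.0)
        env = random_atoms(rng, 38, box=8.0)
        threshold = float(rng.uniform(0.0, 0.8))
        shell = float(rng.uniform(0.1, 1.0))
        got_clash = {(i, j) for i, j, _, _ in detect_clashes(probe, env, threshold)}
        assert got_clash == brute_clashes(probe, env, threshold)
        got_contact = {(i, j) for i, j, _ in count_vdw_contacts(
            probe, env, shell, clash_threshold=threshold)}
        assert got_contact == brute_contacts(probe, env, shell, threshold)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_clash_count_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        probe = random_atoms(rng, 10, box=7.0)
        env = random_atoms(rng, 30, box=7.0)
        counts = [
            len(detect_clashes(probe, env, t)) for t in (0.0, 0.2, 0.4, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_pair_sets_symmetric_under_role_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = random_atoms(rng, 15, box=8.0)
        b = random_atoms(rng, 15, box=8.0)
        fwd = {(i, j) for i, j, _, _ in detect_clashes(a, b, 0.4)}
        rev = {(j, i) for i, j, _, _ in detect_clashes(b, a, 0.4)}
        assert fwd == rev
        fwd_c = {(i, j) for i, j, _ in count_vdw_contacts(a, b, 0.5)}
        rev_c = {(j, i) for i, j, _ in count_vdw_contacts(b, a, 0.5)}
        assert fwd_c == rev_c


def _asn_pair(distance, reciprocal=True):
    """Two Asn residues facing each other, amide groups ``distance`` apart,
    mimicking a reciprocal side-chain hydrogen-bond pair."""
    strand = build_strand(["ASN"], 1)
    res1 = strand[0]
    res1.atoms = [a for a in res1.atoms if a.name in ("N", "CA", "C", "O")]
    res1.atoms.extend(build_side_chain(res1, "ASN", Rotamer("ASN", ChiAngles((-60.0, -30.0), "ASN"))))
    res2 = res1.copy()
    res2.number = 2
    # rotate the partner 180 degrees so ND2 faces OD1 and vice versa
    od1 = res1.atom("OD1").position
    nd2 = res1.atom("ND2").position
    center = 0.5 * (od1 + nd2)
    v = nd2 - od1
    v /= np.linalg.norm(v)
    normal = np.cross(v, [0.0, 0.0, 1.0])
    normal /= np.linalg.norm(normal)
    # 180-degree turn about the perpendicular swaps the OD1/ND2 ends, then
    # the pair is pulled apart along the amide axis
    flip = 2.0 * np.outer(normal, normal) - np.eye(3)
    for atom in res2.atoms:
        atom.position = flip @ (atom.position - center) + center + distance * v
    return res1, res2


class TestHbonds:
    def test_asn_pair_at_2p9_reciprocal(self):
        res1, res2 = _asn_pair(2.9)
        crit = HbondCriteria(3.5, 90.0)
        bonds = detect_hbonds(
            residue_donors(res1, include_backbone=False)
            + residue_donors(res2, include_backbone=False),
            residue_acceptors(res1, include_backbone=False)
            + residue_acceptors(res2, include_backbone=False),
            crit,
        )
        directed = {(d, a) for d, a, _, _ in bonds}
        assert ("ASN1:ND2", "ASN2:OD1") in directed
        assert ("ASN2:ND2", "ASN1:OD1") in directed
        assert len(directed) == 2  # exactly one bond per direction
        # oracle agreement
        oracle = brute_hbonds(
            residue_donors(res1, False) + residue_donors(res2, False),
            residue_acceptors(res1, False) + residue_acceptors(res2, False),
            3.5, 90.0,
        )
        assert directed == oracle

    def test_same_pair_beyond_cutoff_has_no_bond(self):
        res1, res2 = _asn_pair(4.0)
        bonds = detect_hbonds(
            residue_donors(res1, False) + residue_donors(res2, False),
            residue_acceptors(res1, False) + residue_acceptors(res2, False),
            HbondCriteria(3.5, 90.0),
        )
        assert bonds == []

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_hbond_set_matches_oracle_on_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        donors, acceptors = [], []
        for k in range(8):
            d = Atom(name="N", element="N", position=rng.uniform(0, 8, 3), vdw_radius=1.55)
            ante = Atom(name="C", element="C", position=rng.uniform(0, 8, 3), vdw_radius=1.70)
            donors.append((f"D{k}", d, ante))
            a = Atom(name="O", element="O", position=rng.uniform(0, 8, 3), vdw_radius=1.52)
            acceptors.append((f"A{k}", a, ante))
        crit = HbondCriteria(3.5, 90.0)
        got = {(d, a) for d, a, _, _ in detect_hbonds(donors, acceptors, crit)}
        assert got == brute_hbonds(donors, acceptors, 3.5, 90.0)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HbondCriteria(max_donor_acceptor_distance=6.0)
        with pytest.raises(ValueError):
            HbondCriteria(min_angle=200.0)


class TestScoreRotamer:
    def test_identity_substitution_self_consistent(self, hairpin_protomer, params):
        chi = measure_chi(hairpin_protomer.residue(4)).values
        var_rep, wt_rep = score_rotamer(
            hairpin_protomer,
            VariantSpec(4, "GLU", "GLU"),
            Rotamer("GLU", ChiAngles(chi, "GLU")),
            params,
        )
        assert var_rep.n_clashes == 0
        assert var_rep.n_contacts == wt_rep.n_contacts
        assert var_rep.n_hbonds == wt_rep.n_hbonds

    def test_probe_in_empty_environment(self, params):
        lone = build_strand(["GLU"], 1)
        res = lone[0]
        res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
        res.atoms.extend(
            build_side_chain(res, "GLU", Rotamer("GLU", ChiAngles((-60.0, 180.0, 0.0), "GLU")))
        )
        from sodscan.structure import Protomer

        prot = Protomer(chain_id="A", residues=lone)
        var_rep, _ = score_rotamer(
            prot, VariantSpec(1, "GLU", "VAL"),
            Rotamer("VAL", ChiAngles((180.0,), "VAL")), params,
        )
        # only the residue's own backbone is nearby and it is excluded
        assert var_rep.n_clashes == 0

    def test_every_hairpin_val_rotamer_clashes(self, hairpin_protomer, library, params):
        for rot in library.entries["VAL"]:
            var_rep, _ = score_rotamer(
                hairpin_protomer, VariantSpec(4, "GLU", "VAL"), rot, params
            )
            assert var_rep.n_clashes >= 1
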