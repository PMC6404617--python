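"""Rotamer enumeration and ideal-geometry side-chain construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sodscan.fixtures import build_strand, make_mini_hairpin
from sodscan.geometry import dihedral
from sodscan.residues import CHI_ATOMS, chi_count
from sodscan.rotamers import (
    ChiAngles,
    Rotamer,
    VariantSpec,
    build_side_chain,
    enumerate_rotamers,
    grid_rotamers,
    load_default_library,
    replace_residue,
)
from sodscan.structure import Residue
from sodscan.superpose import measure_chi

CHI_BEARING = sorted(aa for aa, defs in CHI_ATOMS.items() if defs)


@pytest.fixture(scope="module")
def backbone():
    return build_strand(["ALA", "ALA", "ALA"], 1)[1]


class TestEnumeration:
    def test_valine_has_three_staggered_rotamers(self, library):
        rots = enumerate_rotamers("VAL", library)
        assert sorted(r.chi.values[0] for r in rots) == [-60.0, 60.0, 180.0]

    def test_glycine_single_trivial_rotamer(self, library):
        rots = enumerate_rotamers("GLY", library)
        assert len(rots) == 1 and rots[0].chi.values == ()

    def test_grid_count_is_step_power_chi(self):
        assert len(grid_rotamers("GLU", 60.0)) == 6**3
        assert len(grid_rotamers("VAL", 30.0)) == 12
        assert len(grid_rotamers("LYS", 120.0)) == 3**4

    def test_backbone_dependent_requires_phi_psi(self, library):
        from sodscan.rotamers import RotamerLibrary

        bd = RotamerLibrary(library.entries, backbone_dependent=True)
        with pytest.raises(ValueError, match="phi_psi"):
            enumerate_rotamers("VAL", bd)
        rots = enumerate_rotamers("VAL", bd, backbone_phi_psi=(-60.0, -45.0))
        # helical bin excludes the +60 chi1 well
        assert all(r.chi.values[0] != 60.0 for r in rots)

    def test_every_amino_acid_covered(self, library):
        for aa in CHI_ATOMS:
            assert enumerate_rotamers(aa, library)


class TestBuild:
    @settings(max_examples=120, derandomize=True)
    @given(
        aa=st.sampled_from(CHI_BEARING),
        seed=st.integers(0, 10_000),
    )
    def test_build_measure_round_trip(self, backbone, aa, seed):
        """measure_chi after build_side_chain is the identity on chi."""
        rng = np.random.default_rng(seed)
        chi = tuple(float(x) for x in rng.uniform(-179.0, 179.0, chi_count(aa)))
        side = build_side_chain(backbone, aa, Rotamer(aa, ChiAngles(chi, aa)))
        res = Residue(
            number=backbone.number,
            amino_acid=aa,
            atoms=[backbone.atom(n).copy() for n in ("N", "CA", "C", "O")] + side,
        )
        measured = measure_chi(res).values
        for got, want in zip(measured, chi):
            assert abs((got - want + 180.0) % 360.0 - 180.0) < 1e-6

    def test_glycine_builds_nothing_alanine_cb_only(self, backbone):
        assert build_side_chain(backbone, "GLY", Rotamer("GLY", ChiAngles((), "GLY"))) == []
        ala = build_side_chain(backbone, "ALA", Rotamer("ALA", ChiAngles((), "ALA")))
        assert [a.name for a in ala] == ["CB"]

    def test_l_chirality_of_cb(self, backbone):
        side = build_side_chain(backbone, "ALA", Rotamer("ALA", ChiAngles((), "ALA")))
        improper = dihedral(
            backbone.atom("N").position,
            backbone.atom("C").position,
            backbone.atom("CA").position,
            side[0].position,
        )
        assert 100.0 < improper < 140.0  # L-amino-acid branch

    def test_glutamine_superimposes_on_glutamate(self, backbone):
        """Gln and Glu at the same chi place the same heavy-atom skeleton;
        only the terminal amide/carboxylate identities differ."""
        chi = (-60.0, 180.0, 30.0)
        glu = {a.name: a.position for a in build_side_chain(
            backbone, "GLU", Rotamer("GLU", ChiAngles(chi, "GLU")))}
        gln = {a.name: a.position for a in build_side_chain(
            backbone, "GLN", Rotamer("GLN", ChiAngles(chi, "GLN")))}
        for name in ("CB", "CG", "CD"):
            assert np.linalg.norm(glu[name] - gln[name]) < 1e-9
        assert np.linalg.norm(glu["OE1"] - gln["OE1"]) < 0.15
        assert np.linalg.norm(glu["OE2"] - gln["NE2"]) < 0.15

    def test_aspartate_reaches_one_bond_shorter_than_glutamate(self, backbone):
        ca = backbone.atom("CA").position

        def max_reach(aa):
            best = 0.0
            for rot in grid_rotamers(aa, 30.0):
                side = build_side_chain(backbone, aa, rot)
                best = max(best, max(float(np.linalg.norm(a.position - ca)) for a in side))
            return best

        glu_reach = max_reach("GLU")
        asp_reach = max_reach("ASP")
        assert glu_reach - asp_reach > 1.0  # roughly one C-C bond

    def test_missing_backbone_atom_is_error(self, backbone):
        broken = Residue(
            number=1, amino_acid="ALA",
            atoms=[backbone.atom("N").copy(), backbone.atom("CA").copy()],
        )
        with pytest.raises(ValueError, match="backbone atom C"):
            build_side_chain(broken, "VAL", Rotamer("VAL", ChiAngles((60.0,), "VAL")))


class TestReplaceResidue:
    def test_glu_to_gly_strips_side_chain(self, hairpin_protomer):
        var = VariantSpec(4, "GLU", "GLY")
        rot = Rotamer("GLY", ChiAngles((), "GLY"))
        out = replace_residue(hairpin_protomer, var, rot)
        res = out.residue(4)
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}

    def test_identity_substitution_rmsd_below_1e3(self, hairpin_protomer):
        chi = measure_chi(hairpin_protomer.residue(4)).values
        out = replace_residue(
            hairpin_protomer,
            VariantSpec(4, "GLU", "GLU"),
            Rotamer("GLU", ChiAngles(chi, "GLU")),
        )
        for atom in hairpin_protomer.residue(4).atoms:
            rebuilt = out.residue(4).atom(atom.name)
            assert np.linalg.norm(rebuilt.position - atom.position) < 1e-3

    def test_glu_to_val_topology(self, hairpin_protomer):
        out = replace_residue(
            hairpin_protomer,
            VariantSpec(4, "GLU", "VAL"),
            Rotamer("VAL", ChiAngles((180.0,), "VAL")),
        )
        side = {a.name for a in out.residue(4).side_chain_atoms()}
        assert side == {"CB", "CG1", "CG2"}

    def test_backbone_bit_identical(self, hairpin_protomer):
        out = replace_residue(
            hairpin_protomer,
            VariantSpec(4, "GLU", "VAL"),
            Rotamer("VAL", ChiAngles((60.0,), "VAL")),
        )
        for res_in, res_out in zip(hairpin_protomer.residues, out.residues):
            for name in ("N", "CA", "C", "O"):
                if res_in.has_atom(name):
                    assert np.array_equal(
                        res_in.atom(name).position, res_out.atom(name).position
                    )

    def test_wild_type_mismatch_rejected(self, hairpin_protomer):
        with pytest.raises(ValueError, match="ALA"):
            replace_residue(
                hairpin_protomer,
                VariantSpec(5, "GLU", "VAL"),
                Rotamer("VAL", ChiAngles((60.0,), "VAL")),
            )

    def test_deletion_directed_to_rule_based_path(self, hairpin_protomer):
        with pytest.raises(ValueError, match="rule-based"):
            replace_residue(
                hairpin_protomer,
                VariantSpec(4, "GLU", "DEL"),
                Rotamer("GLY", ChiAngles((), "GLY")),
            )


class TestVariantSpec:
    @pytest.mark.parametrize(
        "text,pos,wt,sub",
        [
            ("E40G", 40, "GLU", "GLY"),
            ("E133del", 133, "GLU", "DEL"),
            ("G93A", 93, "GLY", "ALA"),
            ("E40Q", 40, "GLU", "GLN"),
        ],
    )
    def test_from_string(self, text, pos, wt, sub):
        v = VariantSpec.from_string(text)
        assert (v.position, v.wild_type, v.substitution) == (pos, wt, sub)

    def test_bad_strings_rejected(self):
        for bad in ("", "40G", "E40", "E40Z", "X40G"):
            with pytest.raises(ValueError):
                VariantSpec.from_string(bad)
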