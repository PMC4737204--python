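"""Space-group operators, expansion, assembly clustering, capsid geometry."""

import itertools
import math

import numpy as np
import pytest

from capsidkit.geometry import dodecahedron_face_normals
from capsidkit.structure_io import StructureError, StructureModel, UnitCell
from capsidkit.symmetry import (SpaceGroupError, apply_symop, capsid_inradius,
                                capsid_pentamer_coms, cell_volume,
                                cluster_assemblies, expand_asymmetric_unit,
                                parse_symop, space_group_operators)
from tests.conftest import make_residue, make_structure


@pytest.fixture(scope="module")
def i23_ops():
    return space_group_operators("I23")


class TestOperators:
    def test_i23_has_24_proper_operators_identity_first(self, i23_ops):
        assert len(i23_ops) == 24
        assert i23_ops[0].is_identity()
        for op in i23_ops:
            r = op.R
            assert np.linalg.det(r) == pytest.approx(1.0)
            np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)

    def test_i23_closed_under_composition_with_inverses(self, i23_ops):
        keyset = {(op.rotation, op.translation) for op in i23_ops}
        assert len(keyset) == 24
        has_inverse = set()
        for a, b in itertools.product(i23_ops, repeat=2):
            c = a.compose(b)
            assert (c.rotation, c.translation) in keyset
            if c.is_identity():
                has_inverse.add((a.rotation, a.translation))
        assert has_inverse == keyset

    def test_xyz_identity(self):
        assert parse_symop("x,y,z").is_identity()

    def test_twofold_squared_is_identity(self):
        op = parse_symop("-x,-y,z")
        assert not op.is_identity()
        assert op.compose(op).is_identity()

    def test_unknown_symbol_rejected(self):
        with pytest.raises(SpaceGroupError):
            space_group_operators("P 21 21 21")

    def test_explicit_operator_list_accepted(self):
        ops = space_group_operators(["x,y,z", "-x,y+1/2,-z"])
        assert len(ops) == 2
        np.testing.assert_allclose(ops[1].t, [0.0, 0.5, 0.0])


class TestApply:
    def test_identity_leaves_coordinates(self, toy_asu, i23_ops):
        out = apply_symop(toy_asu, i23_ops[0], toy_asu.unit_cell)
        np.testing.assert_allclose(out.heavy_coords(),
                                   toy_asu.heavy_coords(), atol=1e-9)

    def test_centering_moves_origin_atom_to_cell_center(self):
        res = make_residue("GLY", 1, [("CA", "C", (0.0, 0.0, 0.0))])
        s = make_structure({"A": [res]},
                           unit_cell=UnitCell(100.0, 100.0, 100.0))
        centering = parse_symop("x+1/2,y+1/2,z+1/2")
        out = apply_symop(s, centering, s.unit_cell)
        np.testing.assert_allclose(next(out.atoms()).coords, [50.0] * 3)

    def test_composition_matches_matrix_product_oracle(self, toy_asu,
                                                       i23_ops):
        op1, op2 = i23_ops[7], i23_ops[15]
        a = apply_symop(apply_symop(toy_asu, op1, toy_asu.unit_cell),
                        op2, toy_asu.unit_cell)
        b = apply_symop(toy_asu, op2.compose(op1), toy_asu.unit_cell)
        np.testing.assert_allclose(a.heavy_coords(), b.heavy_coords(),
                                   atol=1e-8)

    def test_intra_chain_distances_preserved(self, toy_asu, i23_ops):
        ref = toy_asu.chains[0].heavy_coords()
        dref = np.linalg.norm(ref[:, None] - ref[None], axis=-1)
        out = apply_symop(toy_asu, i23_ops[13], toy_asu.unit_cell)
        new = out.chains[0].heavy_coords()
        dnew = np.linalg.norm(new[:, None] - new[None], axis=-1)
        assert np.abs(dref - dnew).max() <= 1e-6


class TestExpansion:
    def test_expansion_multiplies_atoms_24x(self, toy_asu):
        full = expand_asymmetric_unit(toy_asu)
        assert len(full.chains) == 24 * len(toy_asu.chains)
        assert full.n_atoms() == 24 * toy_asu.n_atoms()

    def test_general_position_orbit_has_24_distinct_points(self):
        res = make_residue("GLY", 1, [("CA", "C", (7.1, 13.3, 29.9))])
        s = make_structure({"A": [res]},
                           unit_cell=UnitCell(100.0, 100.0, 100.0),
                           space_group="I 2 3")
        full = expand_asymmetric_unit(s)
        pts = np.round(full.heavy_coords(), 6)
        assert len({tuple(p) for p in pts}) == 24

    def test_expansion_wraps_chain_com_into_cell(self, toy_asu):
        full = expand_asymmetric_unit(toy_asu)
        frac = full.unit_cell.fractionalization_matrix()
        for chain in full.chains:
            com = frac @ chain.heavy_coords().mean(axis=0)
            assert np.all(com >= -1e-9) and np.all(com < 1.0)

    def test_expansion_reproduces_icosahedral_orbit(self, toy_asu,
                                                    toy_capsid):
        """The crystallographic route equals the direct icosahedral one."""
        full = expand_asymmetric_unit(toy_asu)
        ortho = full.unit_cell.orthogonalization_matrix()
        ref = {c.id: c for c in toy_capsid.chains}
        checked = 0
        for chain in full.chains:
            if chain.id not in ref:
                continue
            a = chain.heavy_coords()
            b = ref[chain.id].heavy_coords()
            shift = a.mean(axis=0) - b.mean(axis=0)
            # the wrap shift must be a whole lattice translation
            frac_shift = np.linalg.solve(ortho, shift)
            np.testing.assert_allclose(frac_shift, np.round(frac_shift),
                                       atol=1e-9)
            assert np.abs(a - b - shift).max() <= 1e-3
            checked += 1
        assert checked == 60

    def test_missing_cell_is_an_error(self, toy_asu):
        s = toy_asu.copy()
        s.unit_cell = None
        with pytest.raises(StructureError):
            expand_asymmetric_unit(s)


class TestClustering:
    def test_two_distant_chains_are_singletons(self):
        r1 = make_residue("GLY", 1, [("CA", "C", (0, 0, 0))])
        r2 = make_residue("GLY", 1, [("CA", "C", (100.0, 0, 0))])
        s = make_structure({"A": [r1], "B": [r2]})
        pent = [a for a in cluster_assemblies(s, 4.5, use_pbc=False)
                if a.level == "pentamer"]
        assert len(pent) == 2
        assert all(len(p.members) == 1 for p in pent)

    def test_single_capsid_clusters_as_12_pentamers_1_capsid(self,
                                                             toy_capsid):
        asm = cluster_assemblies(toy_capsid, use_pbc=False)
        pent = [a for a in asm if a.level == "pentamer"]
        caps = [a for a in asm if a.level == "capsid"]
        assert len(pent) == 12
        assert len(caps) == 1 and len(caps[0].members) == 12

    def test_expanded_cell_gives_24_pentamers_2_capsids(self, toy_asu):
        full = expand_asymmetric_unit(toy_asu)
        asm = cluster_assemblies(full)
        pent = [a for a in asm if a.level == "pentamer"]
        caps = [a for a in asm if a.level == "capsid"]
        assert len(pent) == 24
        assert sorted(len(c.members) for c in caps) == [12, 12]

    def test_invariant_to_chain_order(self, toy_capsid):
        reordered = StructureModel(list(reversed(
            [c.copy() for c in toy_capsid.chains])),
            toy_capsid.unit_cell, toy_capsid.space_group)
        a = cluster_assemblies(toy_capsid, use_pbc=False)
        b = cluster_assemblies(reordered, use_pbc=False)
        key = lambda asm: sorted(sorted(x.chain_ids)
                                 for x in asm if x.level == "capsid")
        assert key(a) == key(b)

    def test_nonpositive_cutoff_rejected(self, toy_capsid):
        with pytest.raises(ValueError):
            cluster_assemblies(toy_capsid, contact_cutoff=0.0)


class TestCapsidGeometry:
    def test_ideal_dodecahedron_face_centers_recover_inradius(self):
        coms = 10.0 * dodecahedron_face_normals()
        geo = capsid_inradius(coms)
        assert geo.n_neighbor_pairs == 30
        assert geo.neighbor_distance_d_mean == pytest.approx(10.5146,
                                                             abs=2e-4)
        assert geo.inradius_r == pytest.approx(10.0, rel=1e-9)
        assert geo.neighbor_distance_d_sd <= 1e-9

    def test_toy_capsid_all_30_neighbor_distances_equal(self, toy_capsid,
                                                        toy_params):
        asm = cluster_assemblies(toy_capsid, use_pbc=False)
        cap = next(a for a in asm if a.level == "capsid")
        coms = capsid_pentamer_coms(toy_capsid, cap)
        geo = capsid_inradius(coms)
        assert geo.n_neighbor_pairs == 30
        assert geo.neighbor_distance_d_sd <= 1e-6
        assert geo.inradius_r == pytest.approx(toy_params.inradius,
                                               rel=1e-6)

    def test_single_center_is_insufficient(self):
        with pytest.raises(StructureError):
            capsid_inradius(np.array([[0.0, 0.0, 10.0]]))

    @pytest.mark.parametrize("cell,expected", [
        (UnitCell(180.56, 180.56, 180.56), 180.56 ** 3),
        (UnitCell(1, 1, 1), 1.0),
        (UnitCell(2, 3, 4), 24.0),
    ])
    def test_cell_volume(self, cell, expected):
        assert cell_volume(cell) == pytest.approx(expected, rel=1e-12)

    def test_cubic_cell_volume_value(self):
        # 180.56^3 = 5.8866e6 A^3
        v = cell_volume(UnitCell(180.56, 180.56, 180.56))
        assert v == pytest.approx(180.56 ** 3, rel=1e-12)
        assert v == pytest.approx(5.8866e6, rel=1e-4)
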