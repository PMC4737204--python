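"""Surface areas, contact detection and the association free-energy model."""

import math

import numpy as np
import pytest

from capsidkit.energetics import (SasaError, SolvationParams,
                                  association_free_energy, cavity_waters,
                                  compute_sasa, delta_delta_g,
                                  detect_hbonds, detect_salt_bridges,
                                  sasa_from_arrays, structure_energy,
                                  symmetric_structure_energy)
from capsidkit.geometry import rotation_about_axis
from capsidkit.structure_io import (Atom, Chain, Residue, StructureError,
                                    StructureModel)
from capsidkit.templates import build_peptide
from tests.conftest import make_residue, make_structure


def rigid_copy(structure, rot, t):
    out = structure.copy()
    for a in list(out.atoms()) + list(out.waters):
        a.coords = rot @ a.coords + t
    return out


class TestSasa:
    def test_isolated_carbon_full_sphere(self, sparams):
        s = make_structure({"A": [make_residue("GLY", 1,
                                               [("CA", "C", (0, 0, 0))])]})
        area = compute_sasa(s, sparams)
        assert area[0] == pytest.approx(4 * math.pi * 3.1 ** 2, rel=1e-12)

    def test_fully_caged_atom_has_zero_area(self, sparams):
        specs = [("C1", "C", (0.0, 0.0, 0.0))]
        # icosahedral cage of carbons at 2.0 A swallows the probe-extended
        # sphere of the central atom
        phi = (1 + 5 ** 0.5) / 2
        verts = []
        for a, b in ((1, phi), (phi, 1)):
            for sa in (1, -1):
                for sb in (1, -1):
                    verts += [(0, sa * a, sb * b), (sa * a, sb * b, 0),
                              (sb * b, 0, sa * a)]
        for i, v in enumerate(dict.fromkeys(verts)):
            v = np.array(v, float)
            v = 2.0 * v / np.linalg.norm(v)
            specs.append((f"X{i}", "C", tuple(v)))
        s = make_structure({"A": [make_residue("UNK", 1, specs)]})
        areas = compute_sasa(s, sparams)
        assert areas[0] == 0.0

    def test_unknown_element_named_in_error(self, sparams):
        s = make_structure({"A": [make_residue("UNK", 1,
                                               [("Q1", "Q", (0, 0, 0))])]})
        with pytest.raises(SasaError, match="'Q'"):
            compute_sasa(s, sparams)

    def test_total_area_matches_monte_carlo_oracle(self, sparams):
        """Deterministic spiral quadrature vs dense random-point burial."""
        rng = np.random.default_rng(42)
        n = 40
        coords = rng.uniform(0, 8.0, size=(n, 3))
        radii = np.full(n, 1.7)
        mine = sasa_from_arrays(coords, radii, 1.4, 960).sum()

        # independent brute-force: uniform random directions per atom
        ext = radii + 1.4
        total = 0.0
        m = 100_000
        for i in range(n):
            dirs = rng.normal(size=(m, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts = coords[i] + ext[i] * dirs
            buried = np.zeros(m, dtype=bool)
            for j in range(n):
                if j == i:
                    continue
                d2 = ((pts - coords[j]) ** 2).sum(axis=1)
                buried |= d2 < ext[j] ** 2
            total += 4 * math.pi * ext[i] ** 2 * (~buried).mean()
        assert mine == pytest.approx(total, rel=0.01)

    def test_rotation_invariance_of_total_area(self, toy_asu, sparams):
        a = compute_sasa(toy_asu, sparams)
        rot = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 1.1)
        moved = rigid_copy(toy_asu, rot, np.array([5.0, -3.0, 8.0]))
        b = compute_sasa(moved, sparams)
        np.testing.assert_allclose(a, b, atol=1e-9)


def _two_residue_pair(d, angle_deg=155.0, donor=("ND1", "N"),
                      acceptor=("OE1", "O")):
    """His-like donor and Glu-like acceptor at the given N...O geometry."""
    ante = np.array([0.0, 0.0, 0.0])           # donor antecedent (CG)
    don = np.array([1.35, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)
    acc = don + d * np.array([math.cos(theta), math.sin(theta), 0.0])
    r1 = make_residue("HIS", 1, [("CG", "C", tuple(ante)),
                                 (donor[0], donor[1], tuple(don))])
    r2 = make_residue("GLU", 2, [(acceptor[0], acceptor[1], tuple(acc))],
                      serial_start=10)
    return make_structure({"A": [r1], "B": [r2]})


class TestContacts:
    def test_hbond_at_2p9_and_155_degrees(self):
        recs = detect_hbonds(_two_residue_pair(2.9))
        assert len(recs) == 1
        assert recs[0].kind == "hbond"
        assert recs[0].distance == pytest.approx(2.9)

    def test_hbond_beyond_cutoff(self):
        assert detect_hbonds(_two_residue_pair(3.8)) == []

    def test_hbond_bad_angle_rejected(self):
        assert detect_hbonds(_two_residue_pair(2.9, angle_deg=95.0)) == []

    def test_intra_residue_pairs_excluded(self):
        r = make_residue("ASN", 1, [("ND2", "N", (0, 0, 0)),
                                    ("OD1", "O", (2.9, 0, 0))])
        assert detect_hbonds(make_structure({"A": [r]})) == []

    def test_salt_bridge_at_3A(self):
        r1 = make_residue("ARG", 1, [("NH1", "N", (0, 0, 0))])
        r2 = make_residue("GLU", 2, [("OE1", "O", (3.0, 0, 0))],
                          serial_start=5)
        recs = detect_salt_bridges(make_structure({"A": [r1], "B": [r2]}))
        assert len(recs) == 1 and recs[0].kind == "saltbridge"

    def test_salt_bridge_beyond_cutoff(self):
        r1 = make_residue("ARG", 1, [("NH1", "N", (0, 0, 0))])
        r2 = make_residue("GLU", 2, [("OE1", "O", (5.5, 0, 0))],
                          serial_start=5)
        assert detect_salt_bridges(make_structure({"A": [r1],
                                                   "B": [r2]})) == []

    def test_backbone_nitrogen_is_not_a_salt_bridge_cation(self):
        r1 = make_residue("GLY", 1, [("N", "N", (0, 0, 0))])
        r2 = make_residue("GLU", 2, [("OE1", "O", (3.0, 0, 0))],
                          serial_start=5)
        assert detect_salt_bridges(make_structure({"A": [r1],
                                                   "B": [r2]})) == []

    def test_interassembly_scope_filters_tags(self, toy_capsid):
        inter = detect_salt_bridges(toy_capsid, scope="interassembly")
        assert len(inter) > 0
        assert all(r.inter_assembly for r in inter)


class TestStructureEnergy:
    def test_water_only_structure_has_zero_energy(self, sparams):
        s = StructureModel([], waters=[Atom(1, "O", "O",
                                            np.zeros(3), is_water=True)])
        assert structure_energy(s, sparams) == 0.0

    def test_single_glycine_matches_hand_sum(self, fast_params):
        """G = sum of sigma(class) x per-atom SASA, no contact terms."""
        chain = build_peptide(["GLY"])
        s = StructureModel([chain])
        areas = compute_sasa(s, fast_params)
        sigma = [fast_params.atomic_solvation[
            "apolar" if el == "C" else "polar"]
            for el in ("N", "C", "C", "O")]   # N, CA, C, O order
        expected = float(np.dot(sigma, areas))
        assert structure_energy(s, fast_params) == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_rigid_motion_invariance(self, toy_asu, fast_params):
        g0 = structure_energy(toy_asu, fast_params)
        rot = rotation_about_axis(np.array([0.3, -1.0, 2.0]), 2.3)
        g1 = structure_energy(rigid_copy(toy_asu, rot,
                                         np.array([10.0, 4.0, -7.0])),
                              fast_params)
        assert g1 == pytest.approx(g0, rel=1e-6)


class TestAssociation:
    def test_identity_partition_is_exactly_zero(self, toy_asu, fast_params):
        res = association_free_energy(toy_asu, [toy_asu.copy()],
                                      fast_params)
        assert res.dg_total == 0.0
        assert res.buried_area == 0.0

    def test_zero_contact_dimer_costs_exactly_the_entropy(self, fast_params):
        c1 = build_peptide(["ALA", "GLY"], chain_id="A")
        c2 = build_peptide(["ALA", "GLY"], chain_id="B")
        for a in c2.atoms():
            a.coords = a.coords + np.array([120.0, 0.0, 0.0])
        dimer = StructureModel([c1, c2])
        res = association_free_energy(
            dimer, [dimer.subset(["A"]), dimer.subset(["B"])], fast_params)
        assert res.dg_total == pytest.approx(
            fast_params.rigid_body_entropy, abs=1e-12)
        assert res.buried_area == 0.0
        assert res.n_hbonds == 0 and res.n_saltbridges == 0

    def test_partition_mismatch_rejected(self, toy_asu, fast_params):
        with pytest.raises(StructureError, match="partition"):
            association_free_energy(toy_asu, [toy_asu.subset(["A", "B"])],
                                    fast_params)

    def test_burial_nonnegativity(self, toy_capsid, fast_params):
        pent0 = toy_capsid.subset(
            [c.id for c in toy_capsid.chains[:5]])
        monos = [pent0.subset([c.id]) for c in pent0.chains]
        res = association_free_energy(pent0, monos, fast_params,
                                      check_partition=False)
        assert res.buried_area >= 0.0

    def test_partition_consistency_identity(self, toy_capsid, sparams):
        """dG(capsid->60 monomers) telescopes through the pentamer level."""
        pents = [StructureModel(
            [c.copy() for c in toy_capsid.chains
             if c.id.rsplit("_", 1)[1] == str(k)]) for k in range(12)]
        monos = [StructureModel([c.copy()]) for c in toy_capsid.chains]
        direct = association_free_energy(toy_capsid, monos, sparams)
        via_pent = association_free_energy(toy_capsid, pents, sparams)
        inner = sum(association_free_energy(
            p, [StructureModel([c.copy()]) for c in p.chains], sparams,
            check_partition=False).dg_total for p in pents)
        assert direct.dg_total == pytest.approx(
            via_pent.dg_total + inner, abs=1e-8)

    def test_all_30_interfaces_symmetry_equivalent(self, toy_capsid,
                                                   sparams):
        from capsidkit.symmetry import cluster_assemblies
        asm = cluster_assemblies(toy_capsid, use_pbc=False)
        pent = [a for a in asm if a.level == "pentamer"]
        coms = np.array([p.com for p in pent])
        d = np.linalg.norm(coms[:, None] - coms[None], axis=-1)
        neighbor = d[d > 1.0].min() * 1.05
        vals = []
        for i in range(12):
            for j in range(i + 1, 12):
                if d[i, j] >= neighbor:
                    continue
                ids = pent[i].members + pent[j].members
                pair = toy_capsid.subset(ids)
                res = association_free_energy(
                    pair, [toy_capsid.subset(pent[i].members),
                           toy_capsid.subset(pent[j].members)],
                    sparams, check_partition=False)
                vals.append(res.dg_total)
        vals = np.array(vals)
        assert len(vals) == 30
        assert (vals.max() - vals.min()) <= 1e-6 * abs(vals.mean())

    def test_symmetric_energy_equals_full_evaluation(self, toy_capsid,
                                                     sparams):
        full = structure_energy(toy_capsid, sparams)
        sym = symmetric_structure_energy(toy_capsid, sparams, 12)
        assert sym == pytest.approx(full, rel=1e-9)

    def test_dg_invariant_under_rigid_motion(self, toy_capsid, fast_params):
        pents = [StructureModel(
            [c.copy() for c in toy_capsid.chains
             if c.id.rsplit("_", 1)[1] == str(k)]) for k in range(12)]
        base = association_free_energy(toy_capsid, pents, fast_params,
                                       check_partition=False).dg_total
        rot = rotation_about_axis(np.array([1.0, 1.0, 0.2]), 0.9)
        t = np.array([3.0, -11.0, 6.0])
        moved = rigid_copy(toy_capsid, rot, t)
        moved_pents = [rigid_copy(p, rot, t) for p in pents]
        after = association_free_energy(moved, moved_pents, fast_params,
                                        check_partition=False).dg_total
        assert after == pytest.approx(base, rel=1e-6)


class TestDeltaDeltaG:
    def test_wild_type_vs_marginal_mutant(self):
        assert delta_delta_g(-270.0, -350.0) == pytest.approx(80.0)

    def test_self_difference_zero_and_antisymmetry(self):
        assert delta_delta_g(-5.0, -5.0) == 0.0
        assert delta_delta_g(-1.0, -9.0) == -delta_delta_g(-9.0, -1.0)


class TestCavityWaters:
    def _pocket(self, n_inside, n_outside):
        res = make_residue("SER", 1, [("CA", "C", (0, 0, 0)),
                                      ("CB", "C", (1.5, 0, 0)),
                                      ("OG", "O", (2.2, 1.0, 0))])
        waters = []
        rng = np.random.default_rng(5)
        center = np.array([1.85, 0.5, 0.0])
        for i in range(n_inside):
            waters.append(Atom(100 + i, "O", "O",
                               center + rng.uniform(-1, 1, 3),
                               is_water=True))
        for i in range(n_outside):
            waters.append(Atom(200 + i, "O", "O",
                               center + np.array([30.0 + i, 0, 0]),
                               is_water=True))
        return make_structure({"A": [res]}), waters

    def test_no_waters_gives_zero(self):
        s, _ = self._pocket(0, 0)
        assert cavity_waters(s, [("A", 1)], 5.0) == 0

    def test_counts_only_waters_inside_radius(self):
        s, waters = self._pocket(5, 3)
        s.waters = waters
        assert cavity_waters(s, [("A", 1)], 5.0) == 5

    def test_empty_selection_is_an_error(self):
        s, _ = self._pocket(0, 0)
        with pytest.raises(StructureError):
            cavity_waters(s, [("A", 99)], 5.0)


def test_charging_the_hydrophobic_site_raises_dg(toy_params, fast_params):
    """Charged residues in the hydrophobic cluster destabilise assembly in
    nearly every breathing frame.  The variant mirrors the experimental
    panel's design, where hydrophobic-cluster substitutions always come
    together with an interface polar-site substitution (a lone charged
    residue can be absorbed by a bifurcated bridge to the intact
    arginine)."""
    from capsidkit.ensemble_synth import (EnsembleParams, generate_ensemble,
                                          generate_toy_capsid)
    from capsidkit.mutagenesis import build_mutant, parse_mutation_list
    from capsidkit.pipeline import score_frames
    asu = generate_toy_capsid(toy_params)
    mut = build_mutant(asu, parse_mutation_list("H2R,L3R"))
    eparams = EnsembleParams(n_frames=12, seed=21)
    wt_frames = generate_ensemble(asu, eparams)
    mut_frames = generate_ensemble(mut, eparams)
    wt = [s.dg_capsid for s in score_frames(wt_frames, fast_params)]
    mu = [s.dg_capsid for s in score_frames(mut_frames, fast_params)]
    frac = np.mean([m > w for m, w in zip(mu, wt)])
    assert frac >= 0.95
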