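"""Topology construction: bead counts, geometry, radii, coarse-graining."""

import numpy as np
import pytest

from diabodysim.units import UnitSystem, LINKER_BOND_K, spring_constant_si_to_reduced
from diabodysim.builder import (
    assign_bead_radii,
    build_free_linker_system,
    build_linker,
    build_sbcg_diabody,
    build_sbcg_nanobody,
    build_sph_diabody,
    synthetic_nanobody_cloud,
    NB_TO_PARATOPE,
    NB_TO_CONNECTOR,
)
from diabodysim.fixtures import cluster_cloud
from diabodysim.topology import WCA_CUT, DiabodySystem


class TestSphDiabody:
    @pytest.mark.parametrize("n", [1, 5, 10, 30])
    def test_bead_and_bond_counts(self, n):
        system = build_sph_diabody(n)
        # N linker + NB1,NB2,CB1,CB2,P1,P2 plus one epitope bead
        assert system.n_beads == n + 7
        diabody = [b for b in system.beads if b.group != "epitope"]
        assert len(diabody) == n + 6
        # N-1 linker bonds plus the two connector links
        assert len(system.bonds) == n + 1
        assert len(system.rigid_groups) == 2

    def test_ten_mer_matches_bead_labelling(self):
        system = build_sph_diabody(10)
        names = {b.name for b in system.beads}
        expected = {"NB1", "NB2", "CB1", "CB2", "P1", "P2", "EPI"}
        expected |= {f"L{i}" for i in range(1, 11)}
        assert names == expected

    def test_bead_diameters(self):
        system = build_sph_diabody(10)
        assert system.beads[system.index("NB1")].diameter == 10.0
        assert system.beads[system.index("P1")].diameter == 1.6
        assert system.beads[system.index("CB1")].diameter == 1.0
        for i in range(1, 11):
            assert system.beads[system.index(f"L{i}")].diameter == 1.0

    @pytest.mark.parametrize("n", [1, 10, 40])
    def test_tangent_pole_placement(self, n):
        system = build_sph_diabody(n)
        p = system.positions
        d_np = np.linalg.norm(p[system.index("P1")] - p[system.index("NB1")])
        d_nc = np.linalg.norm(p[system.index("CB1")] - p[system.index("NB1")])
        assert d_np == pytest.approx(NB_TO_PARATOPE)  # 5.8: tangent contact
        assert d_nc == pytest.approx(NB_TO_CONNECTOR)  # 5.5
        # paratope and connector at diametrically opposite poles
        v1 = p[system.index("P1")] - p[system.index("NB1")]
        v2 = p[system.index("CB1")] - p[system.index("NB1")]
        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cos == pytest.approx(-1.0)

    def test_straightening_restraints(self):
        system = build_sph_diabody(10)
        stiff = [t for t in system.angles if t.k > 10]
        assert len(stiff) == 4
        named = {
            tuple(sorted((system.beads[t.i].name, system.beads[t.k_idx].name))
                  + [system.beads[t.j].name])
            for t in stiff
        }
        assert named == {
            ("L10", "P1", "CB1"),  # L10-CB1-P1
            ("L1", "P2", "CB2"),  # P2-CB2-L1
            ("CB2", "L2", "L1"),  # L2-L1-CB2
            ("CB1", "L9", "L10"),  # L9-L10-CB1
        }
        assert all(t.theta0_deg == 180.0 for t in stiff)

    def test_wall_sets(self):
        rep2 = build_sph_diabody(5, "repulsive#2")
        for nb in ("NB1", "NB2"):
            w = rep2.wall_lower[rep2.index(nb)]
            assert w.s_wall == 4.5
            assert w.r_cut == pytest.approx(WCA_CUT * 4.5)
            assert w.kind == "repulsive"
        rep1 = build_sph_diabody(5, "repulsive#1")
        assert rep1.wall_lower[rep1.index("NB1")].s_wall == 4.5
        assert rep1.wall_lower[rep1.index("NB2")].s_wall == 3.0
        att = build_sph_diabody(5, "attractive#1")
        w = att.wall_lower[att.index("NB2")]
        assert w.r_cut == pytest.approx(2.5 * 4.5)
        assert w.epsilon == 1.5
        assert w.kind == "attractive"
        att2 = build_sph_diabody(5, "attractive#2")
        assert att2.wall_lower[att2.index("NB1")].epsilon == 2.5
        # linker and connector beads always repulsive
        for sys_ in (rep2, att, att2):
            for bead in sys_.beads:
                if bead.group in ("linker", "connector"):
                    assert sys_.wall_lower[bead.id].kind == "repulsive"

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            build_sph_diabody(0)
        with pytest.raises(ValueError):
            build_sph_diabody(10, "sticky#9")

    def test_topology_json_roundtrip(self, tmp_path):
        system = build_sph_diabody(4)
        path = tmp_path / "sys.json"
        system.to_json(path)
        back = DiabodySystem.from_json(path)
        assert back.n_beads == system.n_beads
        assert [b.name for b in back.beads] == [b.name for b in system.beads]
        np.testing.assert_allclose(back.positions, system.positions)
        assert len(back.pairs) == len(system.pairs)
        assert back.tether.epsilon == system.tether.epsilon


class TestLinker:
    def test_chain_combinatorics(self):
        beads, bonds, angles = build_linker(10)
        assert (len(beads), len(bonds), len(angles)) == (10, 9, 8)
        assert all(b.diameter == 1.0 and b.mass == 1.0 for b in beads)
        assert all(t.r0 == 1.0 for t in bonds)
        assert all(t.theta0_deg == 180.0 and t.k == 1.8 for t in angles)

    def test_bond_constant_from_si(self):
        # 54 N/m at 300 K, sigma = 3.5 A -> ~1.6e3 kT/sigma^2
        assert LINKER_BOND_K == pytest.approx(1.6e3, rel=0.05)
        assert spring_constant_si_to_reduced(54.0) == LINKER_BOND_K

    def test_bond_fluctuation_about_two_percent(self):
        # sqrt(kT / k_b) / r0 in the 2-3% range quoted for the stiff bond
        rel = np.sqrt(1.0 / LINKER_BOND_K)
        assert 0.02 <= rel <= 0.03

    def test_unit_system_validation(self):
        with pytest.raises(ValueError):
            UnitSystem(sigma_angstrom=-1)
        assert UnitSystem().kT_in_epsilon == pytest.approx(3.0)

    def test_free_chain_builder_excluded_volume_switch(self):
        with_ev = build_free_linker_system(20)
        without = build_free_linker_system(20, excluded_volume=False)
        assert len(with_ev.pairs) > 0
        assert len(without.pairs) == 0
        no_bend = build_free_linker_system(10, bend_k=0)
        assert len(no_bend.angles) == 0


class TestRadii:
    def test_reference_mass_gives_half_sigma(self):
        assert assign_bead_radii([44.05])[0] == pytest.approx(0.5)

    def test_cube_root_scaling(self):
        assert assign_bead_radii([8 * 44.05])[0] == pytest.approx(1.0)

    def test_monotone_and_volume_conserving(self, rng):
        masses = rng.uniform(30, 400, size=25)
        order = np.argsort(masses)
        radii = assign_bead_radii(masses)
        assert np.all(np.diff(radii[order]) >= 0)
        # total bead volume = mass-equivalent number of monomer volumes
        vol = (4 / 3) * np.pi * (radii**3).sum()
        expected = (masses / 44.05).sum() * (4 / 3) * np.pi * 0.5**3
        assert vol == pytest.approx(expected)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            assign_bead_radii([1.0, -2.0])


class TestShapeBasedCoarseGraining:
    def test_single_bead_is_mass_weighted_centroid(self, rng):
        pts = rng.normal(size=(40, 3))
        masses = rng.uniform(1, 10, size=40)
        cg = build_sbcg_nanobody(pts, masses, 1, seed=0)
        expected = (masses[:, None] * pts).sum(axis=0) / masses.sum()
        np.testing.assert_allclose(cg.positions[0], expected, atol=1e-8)
        assert cg.masses[0] == pytest.approx(masses.sum())

    def test_two_clusters_recovered(self):
        centers = [[-8.0, 0, 0], [8.0, 0, 0]]
        pts, masses = cluster_cloud(centers, n_per_cluster=60, spread=0.4, seed=1)
        cg = build_sbcg_nanobody(pts, masses, 2, seed=2)
        # oracle: per-cluster mass centroids (clusters are well separated)
        got = cg.positions[np.argsort(cg.positions[:, 0])]
        for k, c in enumerate(centers):
            sel = np.linalg.norm(pts - np.asarray(c), axis=1) < 4.0
            oracle = pts[sel].mean(axis=0)
            np.testing.assert_allclose(got[k], oracle, atol=0.2)

    def test_protein_scale_mapping_conserves_mass(self):
        coords, masses = synthetic_nanobody_cloud(126, seed=0)
        cg = build_sbcg_nanobody(coords, masses, 40, seed=0)
        assert cg.n_beads == 40
        assert cg.masses.sum() == pytest.approx(masses.sum())
        com_cloud = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        com_beads = (cg.masses[:, None] * cg.positions).sum(axis=0) / cg.masses.sum()
        np.testing.assert_allclose(com_beads, com_cloud, atol=0.5)
        # connected topology
        assert len(cg.bonds) >= 39

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            build_sbcg_nanobody(np.zeros((0, 3)), [], 1)
        pts = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            build_sbcg_nanobody(pts, np.ones(5), 10)

    def test_sbcg_diabody_assembly(self):
        system = build_sbcg_diabody(5, "repulsive#1", n_nb_beads=12, seed=0)
        # two 12-bead nanobodies + 5 linker + CB1/CB2/P1/P2 + epitope
        assert system.n_beads == 2 * 12 + 5 + 4 + 1
        assert len(system.dihedrals) == 2  # anti-rotation restraints
        assert system.rigid_groups == []
        assert system.fixed[system.index("EPI")]
        # CV beads: nbd-1 protein beads + CB1 + P1
        assert len(system.free_nanobody_indices()) == 12 + 2
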