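"""Sampler correctness: determinism, equipartition, rigid bodies, stationarity."""

import numpy as np
import pytest
from scipy import stats

from diabodysim.builder import build_free_linker_system
from diabodysim.topology import (
    Bead,
    BondTerm,
    DiabodySystem,
    PairTable,
    RigidGroup,
    WallSpec,
)
from diabodysim.units import UnitSystem
from diabodysim import engine


def _bare_system(beads, bonds, positions, rigid=None, box=(200.0, 200.0, 200.0)):
    """Minimal wall-less, tether-less system for targeted sampler checks."""
    n = len(beads)
    off = WallSpec(1.0, 0.0, 0.0)
    empty = PairTable(
        i=np.zeros(0, dtype=np.int64), j=np.zeros(0, dtype=np.int64),
        epsilon=np.zeros(0), s=np.zeros(0), r_cut=np.zeros(0),
    )
    return DiabodySystem(
        units=UnitSystem(), beads=beads, positions=np.asarray(positions, float),
        bonds=bonds, angles=[], dihedrals=[], rigid_groups=rigid or [],
        pairs=empty, wall_lower=[off] * n, wall_upper=[off] * n, tether=None,
        box=box, linker_length=0,
    )


def _harmonic_trap_system(k=1.0):
    """Fixed bead at the box centre, mobile bead bound by a k (r0=0) bond."""
    beads = [
        Bead(0, "ANCHOR", 1.0, 1.0, "linker"),
        Bead(1, "PROBE", 1.0, 1.0, "linker"),
    ]
    pos = np.array([[100.0, 100.0, 100.0], [100.2, 100.0, 100.0]])
    system = _bare_system(beads, [BondTerm(0, 1, k, 0.0)], pos)
    system.fixed[0] = True
    return system


class TestDeterminismAndEdges:
    def test_bd_bitwise_reproducible(self, sph10):
        a = engine.run_trajectory(sph10, 20_000, sample_every=500, seed=42)
        b = engine.run_trajectory(sph10, 20_000, sample_every=500, seed=42)
        np.testing.assert_array_equal(a.frames, b.frames)
        c = engine.run_trajectory(sph10, 20_000, sample_every=500, seed=43)
        assert not np.array_equal(a.frames, c.frames)

    def test_mc_reproducible(self, sph10):
        a = engine.sample_equilibrium_mc(sph10, 500, seed=7, sample_every=50)
        b = engine.sample_equilibrium_mc(sph10, 500, seed=7, sample_every=50)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_zero_steps_single_initial_frame(self, sph10):
        traj = engine.run_trajectory(sph10, 0, seed=0)
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.frames[0], sph10.positions)

    def test_timestep_stability_guard(self, sph10):
        with pytest.raises(engine.StabilityError):
            engine.run_trajectory(sph10, 100, dt=0.1, seed=0)
        with pytest.raises(engine.StabilityError):
            engine.run_trajectory(sph10, 100, dt=-1e-4, seed=0)


class TestEquipartition:
    def test_bd_harmonic_trap_variance(self):
        system = _harmonic_trap_system(k=1.0)
        traj = engine.run_trajectory(
            system, 400_000, dt=2e-3, sample_every=50, seed=3, burn_in=5_000
        )
        probe = traj.frames[:, 1, :] - traj.frames[:, 0, :]
        var = probe.var(axis=0).mean()
        assert var == pytest.approx(1.0, rel=0.1)  # kT / k

    def test_mc_harmonic_trap_variance(self):
        system = _harmonic_trap_system(k=1.0)
        traj = engine.sample_equilibrium_mc(
            system, 120_000, seed=5, sample_every=10, burn_in=2_000, amp_free=1.2
        )
        probe = traj.frames[:, 1, :] - traj.frames[:, 0, :]
        var = probe.var(axis=0).mean()
        assert var == pytest.approx(1.0, rel=0.1)

    def test_zero_temperature_relaxation_rate(self):
        # deterministic overdamped limit: x(t) = x0 exp(-k t / gamma)
        system = _harmonic_trap_system(k=1.0)
        system.positions[1] = [102.0, 100.0, 100.0]
        dt, steps = 1e-3, 1000
        traj = engine.run_trajectory(
            system, steps, dt=dt, sample_every=steps, seed=0, kT=0.0
        )
        x = traj.frames[-1, 1, 0] - 100.0
        assert x == pytest.approx(2.0 * np.exp(-steps * dt), rel=1e-2)


class TestRigidBodies:
    def test_internal_geometry_preserved(self, sph10):
        traj = engine.run_trajectory(sph10, 50_000, sample_every=1_000, seed=9)
        for grp in sph10.rigid_groups:
            ids = grp.bead_ids
            ref = sph10.positions[ids]
            d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
            for frame in traj.frames:
                d = np.linalg.norm(
                    frame[ids][:, None] - frame[ids][None, :], axis=-1
                )
                np.testing.assert_allclose(d, d_ref, atol=1e-10)

    def test_mc_preserves_internal_geometry(self, sph10_mc_traj, sph10):
        ids = sph10.rigid_groups[0].bead_ids
        ref = sph10.positions[ids]
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        d = np.linalg.norm(
            sph10_mc_traj.frames[-1][ids][:, None]
            - sph10_mc_traj.frames[-1][ids][None, :],
            axis=-1,
        )
        np.testing.assert_allclose(d, d_ref, atol=1e-10)

    def test_free_sphere_orientation_isotropic(self):
        # rotational diffusion alone: orientations uniform on the unit sphere
        beads = [Bead(0, "NB", 10.0, 1000.0, "nanobody"),
                 Bead(1, "P", 1.6, 4.1, "paratope")]
        pos = np.array([[100.0, 100.0, 100.0], [100.0, 100.0, 105.8]])
        rigid = [RigidGroup("nb", [0, 1], pos - pos.mean(axis=0))]
        system = _bare_system(beads, [], pos, rigid=rigid)
        traj = engine.run_trajectory(
            system, 2_000_000, dt=0.01, sample_every=10_000, seed=17
        )
        u = traj.frames[:, 1, :] - traj.frames[:, 0, :]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # Rayleigh test against uniformity (resultant length of n vectors)
        n = len(u)
        r = np.linalg.norm(u.mean(axis=0))
        z_stat = n * r**2
        assert n >= 150
        assert z_stat < 7.0  # far below rejection for any reasonable level


class TestStationarity:
    def test_tether_never_releases(self, sph10_mc_traj, sph10):
        p2 = sph10_mc_traj.positions_of("P2")
        epi = sph10_mc_traj.positions_of("EPI")
        d = np.linalg.norm(p2 - epi, axis=1)
        assert (d < sph10.tether.r_cut).all()

    def test_ideal_chain_end_to_end(self):
        # freely-jointed 10-mer (bending off): <R^2> = 9 b^2
        system = build_free_linker_system(10, bend_k=0, excluded_volume=False)
        traj = engine.sample_equilibrium_mc(
            system, 60_000, seed=23, sample_every=10, burn_in=2_000
        )
        r = traj.frames[:, -1, :] - traj.frames[:, 0, :]
        r2 = (r**2).sum(axis=1).mean()
        assert r2 == pytest.approx(9.0, rel=0.08)

    def test_mc_and_bd_sample_same_distribution(self, mc_bd_mini_pair):
        system, mc, bd = mc_bd_mini_pair
        end = system.beads[-1].name
        # subsample both series past their correlation times before testing
        z_mc = mc.z_series(end)[::10]
        z_bd = bd.z_series(end)[::80]
        ks = stats.ks_2samp(z_mc, z_bd)
        assert ks.pvalue > 0.01
        assert abs(mc.z_series(end).mean() - bd.z_series(end).mean()) < 0.35


class TestHeightDistribution:
    def test_constant_series_delta(self):
        frames = np.zeros((50, 1, 3))
        frames[:, 0, 2] = 4.2
        traj = engine.Trajectory(frames, ["P1"], 1.0, (10, 10, 10))
        h = engine.bead_height_distribution(traj, "P1", bins=20)
        assert h.mean == pytest.approx(4.2)
        widths = np.diff(h.edges)
        assert (h.density * widths).sum() == pytest.approx(1.0)

    def test_uniform_series(self, rng):
        frames = np.zeros((5000, 1, 3))
        frames[:, 0, 2] = rng.uniform(0, 1, size=5000)
        traj = engine.Trajectory(frames, ["X"], 1.0, (10, 10, 10))
        h = engine.bead_height_distribution(traj, "X", bins=20)
        assert h.mean == pytest.approx(0.5, abs=0.02)
        assert h.quantiles[0.5] == pytest.approx(0.5, abs=0.03)

    def test_unknown_bead(self, sph10_mc_traj):
        with pytest.raises(KeyError):
            engine.bead_height_distribution(sph10_mc_traj, "NOPE")

    def test_sph_cb2_abrupt_lower_cutoff(self, sph10_mc_traj):
        # rigid-sphere tether geometry forbids low connector heights: the CB2
        # distribution has a hard floor set by the nanobody-wall contact
        z = sph10_mc_traj.z_series("CB2")
        assert z.min() > 3.0
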