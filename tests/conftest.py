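"""Shared fixtures: small built systems and short sampled trajectories.

Expensive trajectories are session-scoped and reused across tests; every
generator is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from diabodysim.builder import build_sph_diabody, build_free_linker_system
from diabodysim import engine


@pytest.fixture(scope="session")
def sph10():
    return build_sph_diabody(10, "repulsive#1")


@pytest.fixture(scope="session")
def sph10_mc_traj(sph10):
    return engine.sample_equilibrium_mc(
        sph10, 30_000, seed=11, sample_every=20, burn_in=3_000
    )


@pytest.fixture(scope="session")
def free_chain_mc_traj():
    """Ideal bending chain (no excluded volume), 100 bonds, equilibrated MC."""
    system = build_free_linker_system(101, excluded_volume=False)
    return engine.sample_equilibrium_mc(
        system, 30_000, seed=3, sample_every=20, burn_in=3_000
    )


@pytest.fixture(scope="session")
def mc_bd_mini_pair():
    """MC and BD trajectories of the same wall-tethered flexible chain.

    A 5-bead linker with its first bead pinned above a repulsive wall: the
    base-tilt mode relaxes in tens of Brownian times, so a desk-scale BD run
    holds many independent samples and the two samplers can be compared on
    the stationary distribution of the free end, wall interaction included.
    """
    from diabodysim.builder import build_free_linker_system
    from diabodysim.topology import WallSpec, WCA_CUT

    system = build_free_linker_system(5, box_side=60.0)
    system.fixed[0] = True
    wall = WallSpec(0.8, WCA_CUT * 0.8, 1.0 / 3.0)
    system.wall_lower = [wall] * system.n_beads
    pos = system.positions.copy()
    pos[:, 2] = 3.0 + np.arange(system.n_beads)
    system.positions = pos
    mc = engine.sample_equilibrium_mc(
        system, 120_000, seed=1, sample_every=30, burn_in=10_000
    )
    bd = engine.run_trajectory(
        system, 8_000_000, dt=2.5e-4, sample_every=2_000, seed=2, burn_in=400_000
    )
    return system, mc, bd


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
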