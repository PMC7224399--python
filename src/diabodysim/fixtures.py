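"""Synthetic dataset generators with documented statistical structure.

These realize the analytic reference processes exactly, so every analysis
module can be tested without running a simulation: a two-state Bernoulli frame
process (the uncorrelated model behind the geometric run-length laws), an
Ornstein-Uhlenbeck height series, direct samples from the reflected-Gaussian
tethered-end distribution, and Gaussian cluster clouds for the coarse-grainer.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .theory import GaussianChainModel

__all__ = ["FixtureSpec", "generate_fixture", "two_state_chain",
           "ou_height_series", "ideal_tethered_chain", "cluster_cloud"]


def two_state_chain(p_below: float, n: int, seed: int = 0) -> np.ndarray:
    """IID Bernoulli frame process: True = above threshold, P(below) = p_below."""
    if not 0.0 <= p_below <= 1.0:
        raise ValueError("p_below must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.random(n) >= p_below


def ou_height_series(
    n: int,
    mean: float = 5.0,
    relaxation_time: float = 10.0,
    stddev: float = 2.0,
    dt: float = 1.0,
    seed: int = 0,
    reflect_at_zero: bool = True,
) -> np.ndarray:
    """Ornstein-Uhlenbeck height series (exact discrete update).

    z relaxes to ``mean`` with the given relaxation time and stationary
    standard deviation; optionally reflected at the wall z = 0.  The exact
    AR(1) discretization is used, so the stationary law holds at any dt.
    """
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / relaxation_time)
    s = stddev * np.sqrt(1.0 - a * a)
    z = np.empty(n)
    z[0] = mean + stddev * rng.standard_normal()
    for t in range(1, n):
        z[t] = mean + a * (z[t - 1] - mean) + s * rng.standard_normal()
    if reflect_at_zero:
        z = np.abs(z)
    return z


def ideal_tethered_chain(
    n_kuhn: float, b: float, z_t: float, n: int, seed: int = 0
) -> np.ndarray:
    """Direct samples of the free-end height of a wall-tethered Gaussian chain.

    Exact image-construction sampling: draw z from the free Gaussian
    N(z_t, <d^2>/3) restricted to z > 0 and accept with probability
    1 - exp(-6 z z_t / <d^2>) (for z_t = 0, draw from the wall-tethered law by
    inverse transform of its Rayleigh form).
    """
    model = GaussianChainModel(n_kuhn, b, z_t)
    d2 = model.mean_square_end_to_end
    rng = np.random.default_rng(seed)
    if z_t == 0.0:
        # Rayleigh with scale sqrt(d2/3)
        return np.sqrt(d2 / 3.0) * np.sqrt(-2.0 * np.log(rng.random(n)))
    sd = np.sqrt(d2 / 3.0)
    out = np.empty(n)
    k = 0
    while k < n:
        m = max(2 * (n - k), 64)
        z = z_t + sd * rng.standard_normal(m)
        u = rng.random(m)
        ok = (z > 0) & (u < 1.0 - np.exp(-6.0 * z * z_t / d2))
        take = z[ok][: n - k]
        out[k : k + len(take)] = take
        k += len(take)
    return out


def cluster_cloud(
    centers, n_per_cluster: int = 50, spread: float = 0.5,
    mass: float = 1.0, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs around the given centres, with uniform masses."""
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    pts = np.vstack(
        [c + spread * rng.standard_normal((n_per_cluster, 3)) for c in centers]
    )
    return pts, np.full(len(pts), float(mass))


@dataclass
class FixtureSpec:
    """Named generator plus parameters; generation is deterministic by seed."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: int = 0


_GENERATORS = {
    "two_state_chain": two_state_chain,
    "ou_height_series": ou_height_series,
    "ideal_tethered_chain": ideal_tethered_chain,
    "cluster_cloud": cluster_cloud,
}


def generate_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    try:
        fn = _GENERATORS[spec.generator]
    except KeyError:
        raise KeyError(
            f"unknown generator {spec.generator!r}; choose from {sorted(_GENERATORS)}"
        ) from None
    return fn(**spec.params, seed=spec.seed)
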