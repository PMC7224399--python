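# diabodysim

Coarse-grained models and second-binding kinetics of polymer-linked
two-nanobody molecules (*diabodies*).

Bivalent biologics — two single-domain antibodies (nanobodies) joined by a
flexible polymer linker — gain potency through *avidity*: once one nanobody
binds an epitope on a surface, the tethered partner explores the
neighbourhood and rebinds far faster than a free molecule would. This
package provides the mesoscale toolbox to study that second binding step for
researchers designing such molecules:

- **Model builders** — a rigid-sphere (SPH) diabody (nanobody = 10 σ sphere
  with paratope and connector beads at opposite poles) and a shape-based
  (SBCG) diabody (nanobody = ~40-bead network from a topology-representing
  neural gas over a protein point cloud or PDB file), both tethered through a
  deep LJ well to an epitope site on a wall, in reduced LJ units
  (σ = 3.5 Å, kT = 3ε with ε = 100 K).
- **Samplers** — overdamped Brownian dynamics (rigid bodies via quaternions,
  Stokes-scaled drags) and an equilibrium Metropolis Monte Carlo sampler with
  crankshaft, pivot and tilt moves, both targeting the same Boltzmann
  measure.
- **Free energies** — umbrella sampling over ρ_z (free-nanobody height) and
  ρ_xy (in-plane reach at restrained height) with self-consistent WHAM and a
  flatness metric of the resulting potentials of mean force.
- **Kinetics** — decomposition of paratope height series into flight
  (z ≥ z₀) and residence (z < z₀) events with a recrossing filter, survival
  curves S_f, S_r, on/off rates k_on = [∫S_f dt]⁻¹, k_off = [∫S_r dt]⁻¹,
  exponential-tail constants and the short-time t^(−1/2) diffusion exponent.
- **Polymer theory** — the reflecting-wall tethered Gaussian chain
  P(z) ∝ e^{−3(z−z_t)²/2N_k b²} − e^{−3(z+z_t)²/2N_k b²}, threshold
  probabilities, geometric run-length laws, tail constants
  τ_f = Δt_c/P_<, persistence/Kuhn length estimators, and effective-N_k fits
  of simulated height distributions.

See `docs/methods.md` for the full model description, parameter table and
known limitations.

## Worked example

Build a tethered 10-mer diabody, sample it at equilibrium, and look at the
height statistics of the free paratope P1:

```python
import numpy as np
from diabodysim import (build_sph_diabody, sample_equilibrium_mc,
                        bead_height_distribution, fit_effective_Nk)

system = build_sph_diabody(10, "repulsive#1")   # 17 beads incl. epitope
traj = sample_equilibrium_mc(system, 60_000, seed=1, sample_every=20,
                             burn_in=6_000)
h = bead_height_distribution(traj, "P1", bins=60)
print(f"mean P1 height: {h.mean:.2f} sigma")
fit = fit_effective_Nk(h.density, h.edges, b=3.0, z_t=7.5, linker_length=10)
print(f"effective Kuhn segments: {fit.n_kuhn_eff:.1f} "
      f"(naive contour guess {fit.naive_guess:.1f})")
```

```
mean P1 height: 15.29 sigma
effective Kuhn segments: 51.9 (naive contour guess 7.1)
```

The free paratope of the 10-mer diabody sits ~15 σ above the wall on
average, and its height distribution is far wider than the bare-polymer
contour estimate (51.9 effective Kuhn segments versus 7.1): the wall pushes
the bulky free nanobody entropically upward, the hallmark of these composite
molecules.

The same workflow runs from a shell:

```sh
diabodysim build --model sph -N 10 --wall-set "repulsive#1" -o top.json
diabodysim mc -t top.json --sweeps 60000 --burn-in 6000 -o run1
diabodysim kinetics --series run1.xyz --bead P1 --z0 3.5 -o kin1
diabodysim pmf windows --min 3 --max 30 --spacing 0.5 | wc -l   # 55
```

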