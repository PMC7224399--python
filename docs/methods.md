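# Methods

## The model

`diabodysim` implements mesoscale models of a *diabody*: two nanobodies (single
domain antibody fragments) joined by a flexible polymer linker, tethered by
one paratope to an epitope site on a flat wall. The scientific question the
model addresses is the kinetics and thermodynamics of the *second* binding
event — once one nanobody is bound, how does the free nanobody explore the
surface, and how do linker length, nanobody shape and weak non-specific
wall attraction control the encounter (on) and escape (off) rates?

All quantities are in reduced Lennard-Jones units: lengths in
σ = 3.5 Å (one linker monomer), energies internally in kT at 300 K
(the model's native energy unit is ε = 100 K, so kT = 3ε), times in the
Brownian time τ_B = γσ²/kT of a unit-drag bead. The reduced-time → ns
mapping is deliberately left unset: the source protocol's friction constant
is unknown, so only dimensionless and equilibrium quantities are meaningful.

### Bead models

**SPH** — each nanobody is one rigid sphere of diameter 10 σ carrying a
connector bead (diameter 1) and a paratope bead (diameter 1.6) at
diametrically opposite poles, placed at tangent contact (centre distance =
sphere radius + bead radius, i.e. 5.5 and 5.8 σ). Sphere + connector +
paratope form a rigid body.

**SBCG** — each nanobody is a flexible network of ~40 beads produced by a
topology-representing neural gas (rank-based soft-max codebook updates with
exponentially decaying learning rate and neighbourhood range, polished by
mass-weighted Lloyd steps so each bead is the mass centroid of its Voronoi
domain). Bead radii follow mass-proportional volume,
r = 0.5 σ (m/m_PEG)^{1/3} against the PEG monomer mass (44 Da). Bonds follow
atomistic connectivity when supplied, otherwise Voronoi adjacency. The
fluctuation-matched bond/angle constants of the original shape-based scheme
require an atomistic trajectory, which is out of scope here; the package
defaults are k_bond = 100 kT/σ² and k_angle = 10 kT/rad² at the built
geometry. Since no protein structure ships with the package, tests use a
synthetic prolate-spheroid point cloud (semi-axes 6.5 × 4.4 × 4.4 σ,
geometric-mean diameter ≈ 10 σ so the two models are size-matched); any PDB
file can be supplied instead via `io.read_pdb_coords`.

**Linker** — N unit-diameter, unit-mass beads. Bonds are stiff harmonic
springs, ½k(r−r₀)² with k = 54 N/m → ≈1.6·10³ kT/σ² (bond fluctuations
≈ 2.5 %). Bending uses the discrete Kratky–Porod (cosine) potential
k_θ(1 + cos θ) with k_θ = 1.8 kT, whose quadratic expansion about θ = 180° is
the harmonic form ½k_θ(θ−θ₀)² with the same coefficient. The cosine form is
the default because it is the potential for which the chain's persistence
length obeys the classic freely-jointed-chain-with-bending result
⟨cos γ⟩ = coth(βk_θ) − 1/(βk_θ), giving ℓ_p ≈ 1.45 σ and Kuhn length
b = 2ℓ_p ≈ 3 σ — the stiffness the model is built around (PEG-like linker).
The harmonic style is available (`angle_style="harmonic"`), but note it
yields a noticeably stiffer chain at this coefficient (ℓ_p ≈ 2.0 σ).

**Interactions** — excluded volume between all bead pairs (except bonded
pairs and pairs inside one rigid body) is WCA: LJ with s_ij = sum of radii,
cut and shifted at 2^{1/6}s_ij. Repulsive well depths (bead–bead and
repulsive walls) use the native LJ energy unit, ε = 100 K = kT/3. The box is
periodic in x and y only; minimum-image displacements are used in every term,
so the energy is exactly invariant under lattice translations. The lower
z-wall interacts with each bead through a 12-6 wall potential cut at
2^{1/6}s_wall (repulsive) or 2.5 s_wall (attractive); the upper wall is
always repulsive with s_wall = 0.8 σ. The four wall parameter sets:

| set          | s_wall nbd-1/nbd-2 | cutoff            | ε (kT) |
|--------------|--------------------|-------------------|--------|
| repulsive#1  | 4.5 / 3.0          | 2^{1/6} s_wall    | 1/3    |
| repulsive#2  | 4.5 / 4.5          | 2^{1/6} s_wall    | 1/3    |
| attractive#1 | 4.5 / 4.5          | 2.5 s_wall        | 1.5    |
| attractive#2 | 4.5 / 4.5          | 2.5 s_wall        | 2.5    |

In the attractive sets the nanobody and paratope beads feel the attraction;
linker and connector beads always interact repulsively (s_wall = 0.8 σ).

**Tether** — the epitope is modelled as a fixed binding *site* on the wall
plane (a zero-size anchor at z = 0), attracting the bound paratope through a
deep LJ well (ε = 20 kT, s = paratope radius, cutoff 2.5 s). The bound
paratope therefore rests essentially at its own wall-contact height
(≈ 0.9 σ). The well is deep enough that no detachment ever occurs, which is
verified by a test. **Junction restraints** — the four angles that join the
linker to the nanobody poles (e.g. L_N–CB1–P1 and P2–CB2–L1) are restrained
to 180° with a harmonic coefficient 10× the linker bending (18 kT); SBCG
nanobodies additionally carry one harmonic dihedral each (10 kT/rad²) that
stops rotation about their long axis.

**Geometry note.** The tangent-pole construction fixes the paratope→connector
span of one nanobody at 11.3 σ. With s_wall = 4.5 σ the tethered sphere's
centre cannot drop below ≈ 4.3 σ, which places a hard floor of ≈ 7.3 σ under
the tethered connector bead CB2; the published mean CB2 height of 7.5 σ is
therefore only reachable with the softer s_wall = 3.0 tethered-nanobody wall
of repulsive set #1, which the equilibrium-height computations use.

## Samplers

**Brownian dynamics** — first-order Euler–Maruyama in the overdamped limit,
x ← x + (F/γ)dt + √(2 kT dt/γ)ξ, with γ = 1 per free bead. Rigid bodies
translate with the net force and rotate with the net torque about their
centre of mass; drags follow Stokes scaling, γ_t = d and γ_r = d³ for a body
of diameter d. Orientations are unit quaternions; positions are always
rebuilt as com + R(q)·(body-frame coordinates), so internal distances are
preserved to machine precision. Default timestep 10⁻⁴ τ_B (stability bound
2γ/k_bond ≈ 1.25·10⁻³); per-step displacements are clamped at 0.25 σ, which
is inactive in normal operation and only prevents runaway from rare
noise-induced bond overstretching. Forces below 0.3 s_ij are capped at their
value at the capping radius (with linear energy continuation), so rare
overlaps cannot produce unbounded forces.

**Monte Carlo** — Metropolis sampling of the same Boltzmann measure, used for
all equilibrium observables. One sweep mixes: single-bead displacements
(±0.12 σ), rigid-group translations and rotations (about the centre of mass
or about the group's anchored bead — the latter samples the tilt of the
tethered nanobody without fighting the tether), crankshaft rotations of
linker sub-chains (bond-length preserving, the efficient move for a
stiff-bonded chain), pivot rotations of the chain tail together with the
free-nanobody arm, and base-tilt rotations of the whole molecule about the
anchored paratope (tether energy invariant). All proposals are symmetric, so
detailed balance holds. The MC and BD samplers are cross-checked against
each other on a small flexible system (two-sample KS test on the paratope
height distribution).

A note on time scales: with Stokes drags the orientational relaxation of a
10 σ rigid nanobody is ~10³ τ_B. Desk-scale BD trajectories (10³–10⁴ τ_B)
therefore resolve the *short-time* kinetics of the paratope (recrossing
statistics, the t^{-1/2} survival regime) but not converged mean
flight/residence times, which in the source protocol required pooling 25
tethered copies over 30 μs trajectories. Mean-rate *trends* are accordingly
checked at the level of converged equilibrium occupancies P(z < z₀)
(the configurational factor of the rates in the uncorrelated-frame
description below), not of BD event means.

## Umbrella sampling and WHAM

Collective variables: ρ_z, the height of the free nanobody's centre of mass
(rigid group for SPH, all nbd-1 beads + CB1 + P1 for SBCG); ρ_xy, the
in-plane distance from the tether point to that centre of mass, sampled with
ρ_z restrained (50 kT/σ² at 5 σ by default). Windows are harmonic biases
(default 10 kT/σ²) on an inclusive arithmetic grid; starting structures come
from sequential dragging with an equilibration stage per centre. Window
series are subsampled at their integrated autocorrelation time, binned
(0.25 σ default) and combined by self-consistent WHAM iteration to 10⁻⁷ kT;
windows whose sampled mean cannot reach their centre (sterically excluded)
are flagged and skipped, and disjoint window sets raise an error naming the
gap. For ρ_xy the 2D volume element contributes −kT ln ρ of entropy to
−kT ln P(ρ); `wham(..., radial_jacobian=True)` removes it so the profile is
the free energy of the in-plane displacement vector. The flatness statistic
is the mean of ρ_xy/L over the region with PMF ≤ 1 kT (L = tether→paratope
contour reach), plus the extent of that region.

## Flight/residence kinetics

The free paratope's height series is split at z₀ = 3.5 σ into flight
(z ≥ z₀) and residence (z < z₀) stretches. Stretches shorter than a minimum
duration are *merged* into the enclosing event, shortest first (the two
neighbours of an absorbed run share a kind and coalesce), guaranteeing strict
alternation; the first and last (trajectory-truncated) events are marked
censored and excluded from duration statistics by default. Survival curves
are the empirical complementary cumulative distributions; their time
integrals equal the mean durations identically, and the on/off rates are the
reciprocals, with bootstrap (1000 resamples) errors. Exponential tails are
fitted by weighted linear regression of ln S(t) (weights ∝ number of
surviving events); the short-time power-law exponent by log-log least
squares with a curvature diagnostic that flags non-power-law input. In the
uncorrelated-frame description, run lengths above/below threshold are
geometric, P_a(k) = P_>(1−P_<)^{k−1}P_<, giving tail constants
τ_f = Δt_c/P_< and τ_r = Δt_c/P_> with Δt_c the frame correlation time —
these close the loop between the event statistics and the analytic chain
model and are verified against each other in tests.

## Analytic chain references

The reflecting-wall tethered Gaussian chain (N_k Kuhn segments of length b,
tether height z_t) has end-height density built by image construction with an
erf normalization; the z_t → 0 limit is the wall-tethered form
P(z) = (3z/⟨d²⟩)exp(−3z²/2⟨d²⟩), ⟨d²⟩ = N_k b². Threshold probabilities,
run-length laws and tail constants follow in closed form. The persistence
length estimator fits exp(−s·b₀/ℓ_p) to the bond-direction correlation
C(s) over separations 1–15 (weighted log-linear fit); it is validated
against a direct (rejection) sampler of the discrete worm-like measure. The
effective-polymer fit adjusts N_k in the reflected-Gaussian density (b and
z_t fixed) by least squares against a simulated height histogram and reports
the naive contour guess (N + 2r)/b alongside.

## Problem sizes and what desk-scale results do and do not show

Default study conditions reproduce the source protocol's parameters (bead
sizes, force constants, wall sets, z₀ = 3.5 σ, window spacing 0.5 σ).
Equilibrium quantities in the acceptance script use single-copy MC with
1.2–1.5·10⁵ sweeps after burn-in (convergence checked by stable
block means); the t^{-1/2} exponent uses two pooled BD copies of
~1.75·10³ τ_B each. The synthetic SBCG spheroid preserves the size and
aspect of the real nanobody but not its surface detail, so SPH-vs-SBCG
comparisons here probe shape/flexibility at the coarsest level only.
Deviations that persist at full sampling are documented where they occur:
the tethered-connector mean height converges ≈ 1.3 σ above the published
value (residual sensitivity to the unspecified tether construction), and the
effective Kuhn number of the 40-mer converges near 80 against the published
~108 (the published value is only approached under a bending-stiffness
convention that contradicts the model's own stated persistence length; the
package keeps the self-consistent ℓ_p ≈ 1.5 σ linker).

## Known limitations

- No hydrodynamic interactions, no inertia, no electrostatics (all beads
  neutral), flat walls only.
- Absolute times in physical units are not available by design (unknown
  source friction); kinetic outputs are in τ_B or dimensionless.
- Mean flight/residence rates from BD require far more sampling than
  desk-scale runs provide (see Samplers); only short-time statistics and
  equilibrium occupancies are quantitative at desk scale.
- The SBCG bonded constants are package defaults, not fluctuation-matched to
  an atomistic trajectory.
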