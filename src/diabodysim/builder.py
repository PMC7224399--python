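"""Constructors for SPH and SBCG diabody systems.

The SPH (sphere) model represents each nanobody as a rigid sphere of diameter
10 sigma decorated with a connector bead (diameter 1) and a paratope bead
(diameter 1.6) at diametrically opposite poles; the two nanobodies are bridged
by a freely-jointed bead-spring linker of N unit beads.  The SBCG model
replaces each sphere by ~40 beads produced by a topology-representing neural
gas over a protein point cloud, preserving the protein's shape.

The tethered geometry is standardized: nbd-2 (NB2/CB2/P2) is anchored to the
lower z-wall through a deep LJ attraction between P2 and a fixed epitope bead,
the linker runs CB2-L1-...-LN-CB1, and nbd-1 (NB1/CB1/P1) is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import UnitSystem, LINKER_BOND_K, LINKER_BEND_K
from .topology import (
    WCA_CUT,
    AngleTerm,
    Bead,
    BondTerm,
    DihedralTerm,
    DiabodySystem,
    RigidGroup,
    TetherSpec,
    WallSpec,
    build_pair_table,
)

# geometric constants of the SPH nanobody (sigma)
NB_DIAMETER = 10.0
PARATOPE_DIAMETER = 1.6
CONNECTOR_DIAMETER = 1.0
# tangent placement: centre distances from the sphere centre along the polar axis
NB_TO_PARATOPE = NB_DIAMETER / 2 + PARATOPE_DIAMETER / 2  # 5.8
NB_TO_CONNECTOR = NB_DIAMETER / 2 + CONNECTOR_DIAMETER / 2  # 5.5

#: straightening restraints use a 10x stiffer coefficient than the linker bending
RESTRAINT_BEND_K = 10.0 * LINKER_BEND_K
#: default tether well depth in kT; deep enough that no detachment occurs
TETHER_EPSILON = 20.0
#: wall parameters for linker/connector (and default for every non-nanobody bead)
SMALL_BEAD_S_WALL = 0.8

#: repulsive interactions (walls, bead-bead WCA) use the native LJ energy unit
#: epsilon = 100 K, i.e. kT/3 at room temperature; attractive wall depths are
#: quoted directly in kT.
EPS_REPULSIVE = 1.0 / 3.0

# Table-1 wall parameter sets: (s_wall nbd-1, s_wall nbd-2, attractive?, eps_kT)
WALL_SETS = {
    "repulsive#1": (4.5, 3.0, False, EPS_REPULSIVE),
    "repulsive#2": (4.5, 4.5, False, EPS_REPULSIVE),
    "attractive#1": (4.5, 4.5, True, 1.5),
    "attractive#2": (4.5, 4.5, True, 2.5),
}


def _wall_spec(s: float, attractive: bool, eps: float) -> WallSpec:
    cut = 2.5 * s if attractive else WCA_CUT * s
    return WallSpec(s_wall=s, r_cut=cut, epsilon=eps)


def build_linker(
    n: int, angle_style: str = "cosine", offset: int = 0, name_prefix: str = "L"
) -> tuple[list[Bead], list[BondTerm], list[AngleTerm]]:
    """Bead/bond/angle lists for an N-bead freely-jointed linker.

    N unit-diameter, unit-mass beads; N-1 stiff harmonic bonds at r0 = 1 sigma
    (54 N/m in physical units); N-2 bending terms with theta0 = 180 deg and
    coefficient 1.8 kT.  Bead ids start at ``offset``.
    """
    if n < 1:
        raise ValueError("linker length must be >= 1")
    beads = [
        Bead(offset + i, f"{name_prefix}{i + 1}", 1.0, 1.0, "linker") for i in range(n)
    ]
    bonds = [
        BondTerm(offset + i, offset + i + 1, LINKER_BOND_K, 1.0) for i in range(n - 1)
    ]
    angles = [
        AngleTerm(offset + i, offset + i + 1, offset + i + 2, LINKER_BEND_K, 180.0, angle_style)
        for i in range(n - 2)
    ]
    return beads, bonds, angles


def default_box(n: int) -> tuple[float, float, float]:
    lx = 5.0 * (n + 12)
    lz = max(2.0 * (n + 12), n + 30.0)
    return (lx, lx, lz)


def build_sph_diabody(
    n: int,
    wall_set: str = "repulsive#2",
    box: tuple[float, float, float] | None = None,
    angle_style: str = "cosine",
    tether_epsilon: float = TETHER_EPSILON,
) -> DiabodySystem:
    """Rigid-sphere diabody with an N-bead linker, tethered to the lower wall.

    Bead order: P2, NB2, CB2, L1..LN, CB1, NB1, P1, EPI (N+7 beads, of which
    N+6 belong to the diabody).  Raises ``ValueError`` for N < 1 or an unknown
    wall set.
    """
    if n < 1:
        raise ValueError("linker length must be >= 1")
    if wall_set not in WALL_SETS:
        raise ValueError(f"unknown wall set {wall_set!r}; choose from {sorted(WALL_SETS)}")
    s1, s2, attractive, eps_w = WALL_SETS[wall_set]

    nb_mass = (NB_DIAMETER / 1.0) ** 3  # volume scaling relative to a linker bead
    p_mass = PARATOPE_DIAMETER**3

    beads = [
        Bead(0, "P2", PARATOPE_DIAMETER, p_mass, "paratope"),
        Bead(1, "NB2", NB_DIAMETER, nb_mass, "nanobody"),
        Bead(2, "CB2", CONNECTOR_DIAMETER, 1.0, "connector"),
    ]
    l_beads, l_bonds, l_angles = build_linker(n, angle_style, offset=3)
    beads += l_beads
    i_cb1, i_nb1, i_p1, i_epi = n + 3, n + 4, n + 5, n + 6
    beads += [
        Bead(i_cb1, "CB1", CONNECTOR_DIAMETER, 1.0, "connector"),
        Bead(i_nb1, "NB1", NB_DIAMETER, nb_mass, "nanobody"),
        Bead(i_p1, "P1", PARATOPE_DIAMETER, p_mass, "paratope"),
        Bead(i_epi, "EPI", 1.0, 1.0, "epitope"),
    ]

    i_l1, i_ln = 3, n + 2
    bonds = l_bonds + [
        BondTerm(2, i_l1, LINKER_BOND_K, 1.0),  # CB2-L1
        BondTerm(i_ln, i_cb1, LINKER_BOND_K, 1.0),  # LN-CB1
    ]

    # straightening restraints at the linker/nanobody junctions (theta0=180)
    angles = list(l_angles)
    restraints = [(i_ln, i_cb1, i_p1), (0, 2, i_l1)]  # LN-CB1-P1, P2-CB2-L1
    if n >= 2:
        restraints += [(3 + 1, 3, 2), (i_ln - 1, i_ln, i_cb1)]  # L2-L1-CB2, L(N-1)-LN-CB1
    for (a, b, c) in restraints:
        angles.append(AngleTerm(a, b, c, RESTRAINT_BEND_K, 180.0, "harmonic"))

    # initial straight vertical stack, tether point at the box centre
    if box is None:
        box = default_box(n)
    cx, cy = box[0] / 2.0, box[1] / 2.0
    tether_s = PARATOPE_DIAMETER / 2  # point-site epitope on the wall plane
    z_p2 = WCA_CUT * tether_s
    pos = np.zeros((n + 7, 3))
    pos[:, 0] = cx
    pos[:, 1] = cy
    pos[0, 2] = z_p2
    pos[1, 2] = z_p2 + NB_TO_PARATOPE
    pos[2, 2] = z_p2 + NB_TO_PARATOPE + NB_TO_CONNECTOR
    for i in range(n):
        pos[3 + i, 2] = pos[2, 2] + (i + 1)
    pos[i_cb1, 2] = pos[i_ln, 2] + 1.0
    pos[i_nb1, 2] = pos[i_cb1, 2] + NB_TO_CONNECTOR
    pos[i_p1, 2] = pos[i_nb1, 2] + NB_TO_PARATOPE
    pos[i_epi, 2] = 0.0

    rigid = []
    for name, ids in (("nbd2", [0, 1, 2]), ("nbd1", [i_cb1, i_nb1, i_p1])):
        m = np.array([beads[i].mass for i in ids])
        r = pos[ids]
        com = (m[:, None] * r).sum(axis=0) / m.sum()
        rigid.append(RigidGroup(name, list(ids), r - com))

    exclusions = set()
    for t in bonds:
        exclusions.add((min(t.i, t.j), max(t.i, t.j)))
    for g in rigid:
        ids = g.bead_ids
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                exclusions.add((min(ids[a], ids[b]), max(ids[a], ids[b])))
    pairs = build_pair_table(beads, exclusions)

    wall_lower, wall_upper = [], []
    for b in beads:
        if b.group == "epitope":
            wall_lower.append(WallSpec(1.0, 0.0, 0.0))
            wall_upper.append(WallSpec(1.0, 0.0, 0.0))
            continue
        if b.name == "NB1":
            wall_lower.append(_wall_spec(s1, attractive, eps_w))
        elif b.name == "NB2":
            wall_lower.append(_wall_spec(s2, attractive, eps_w))
        elif b.group == "paratope" and attractive:
            # weak non-specific attraction also acts on the paratopes
            wall_lower.append(_wall_spec(SMALL_BEAD_S_WALL, True, eps_w))
        else:
            # linker and connector beads always interact repulsively
            wall_lower.append(_wall_spec(SMALL_BEAD_S_WALL, False, EPS_REPULSIVE))
        wall_upper.append(_wall_spec(SMALL_BEAD_S_WALL, False, EPS_REPULSIVE))

    tether = TetherSpec(
        paratope=0, epitope=i_epi, epsilon=tether_epsilon, s=tether_s, r_cut=2.5 * tether_s
    )
    fixed = np.zeros(len(beads), dtype=bool)
    fixed[i_epi] = True
    return DiabodySystem(
        units=UnitSystem(),
        beads=beads,
        positions=pos,
        bonds=bonds,
        angles=angles,
        dihedrals=[],
        rigid_groups=rigid,
        pairs=pairs,
        wall_lower=wall_lower,
        wall_upper=wall_upper,
        tether=tether,
        box=box,
        linker_length=n,
        fixed=fixed,
        metadata={"model": "SPH", "wall_set": wall_set, "angle_style": angle_style},
    )


def build_free_linker_system(
    n_beads: int,
    angle_style: str = "cosine",
    box_side: float | None = None,
    excluded_volume: bool = True,
    bend_k: float | None = None,
) -> DiabodySystem:
    """An isolated linker chain in a large box with no walls or tether.

    Used for equilibrium chain statistics (persistence length, ideal-chain
    end-to-end checks).  Wall interactions are switched off.  With
    ``excluded_volume=False`` the chain is the ideal freely-jointed chain with
    angle bending only -- the model for which the persistence length is a pure
    property of the bending Hamiltonian (swelling by self-avoidance otherwise
    adds a slowly decaying tail to the bond-direction correlations).
    ``bend_k`` overrides the default bending coefficient (1.8 kT); 0 removes
    the bending terms entirely.
    """
    beads, bonds, angles = build_linker(n_beads, angle_style)
    if bend_k is not None:
        if bend_k == 0:
            angles = []
        else:
            for t in angles:
                t.k = float(bend_k)
    if box_side is None:
        box_side = 4.0 * n_beads + 20.0
    box = (box_side, box_side, box_side)
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = box[0] / 2
    pos[:, 1] = box[1] / 2
    pos[:, 2] = box[2] / 2 - n_beads / 2 + np.arange(n_beads)
    if excluded_volume:
        excl = {(t.i, t.j) for t in bonds}
        pairs = build_pair_table(beads, excl)
    else:
        pairs = build_pair_table(beads, {(a, b) for a in range(n_beads) for b in range(a + 1, n_beads)})
    off = WallSpec(1.0, 0.0, 0.0)
    return DiabodySystem(
        units=UnitSystem(),
        beads=beads,
        positions=pos,
        bonds=bonds,
        angles=angles,
        dihedrals=[],
        rigid_groups=[],
        pairs=pairs,
        wall_lower=[off] * n_beads,
        wall_upper=[off] * n_beads,
        tether=None,
        box=box,
        linker_length=n_beads,
        metadata={"model": "free_linker", "angle_style": angle_style},
    )


# ---------------------------------------------------------------------------
# radii from masses
# ---------------------------------------------------------------------------

#: PEG monomer mass in Da, the reference for protein-bead radii
PEG_MONOMER_MASS = 44.05


def assign_bead_radii(masses, reference_mass: float = PEG_MONOMER_MASS) -> np.ndarray:
    """Mass-proportional-volume radii: r_i = 0.5 sigma (m_i / m_ref)^(1/3).

    A bead with the reference (PEG monomer) mass gets the linker bead radius
    0.5 sigma; total bead volume then equals the mass-equivalent number of
    monomer volumes.
    """
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0) or reference_mass <= 0:
        raise ValueError("masses must be positive")
    return 0.5 * (m / reference_mass) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# shape-based coarse graining (topology-representing neural gas)
# ---------------------------------------------------------------------------


@dataclass
class CoarseGrainResult:
    """Output of the neural-gas coarse-graining of a point cloud."""

    positions: np.ndarray
    masses: np.ndarray
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    assignment: np.ndarray = field(repr=False)

    @property
    def n_beads(self) -> int:
        return len(self.masses)


def build_sbcg_nanobody(
    coords,
    masses,
    n_beads: int,
    seed: int = 0,
    connectivity=None,
    n_epochs: int = 200,
) -> CoarseGrainResult:
    """Coarse-grain a weighted point cloud into ``n_beads`` beads.

    Runs a Martinetz-style topology-representing neural gas: codebook vectors
    are updated with a rank-based soft-max learning rule under exponentially
    decaying learning rate and neighbourhood range, then polished with a few
    mass-weighted Lloyd steps so each bead sits at the mass centroid of its
    Voronoi domain (total mass is conserved exactly).

    Bonds follow the supplied atomistic ``connectivity`` (pairs of point
    indices) where available -- a bond joins two beads whenever their domains
    contain bonded atoms -- and otherwise the competitive-Hebb adjacency of the
    Voronoi domains.  Angles are all connected bead triples.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or len(x) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0) or len(m) != len(x):
        raise ValueError("masses must be positive, one per point")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if n_beads > len(x):
        raise ValueError("n_beads cannot exceed the number of input points")

    rng = np.random.default_rng(seed)
    w = x[rng.choice(len(x), size=n_beads, replace=False)].copy()

    t_max = max(1, n_epochs * len(x))
    lam_i, lam_f = max(n_beads / 2.0, 1e-9), 0.01
    eps_i, eps_f = 0.3, 0.05
    order = rng.integers(0, len(x), size=t_max)
    for t, idx in enumerate(order):
        frac = t / t_max
        lam = lam_i * (lam_f / lam_i) ** frac
        eps = eps_i * (eps_f / eps_i) ** frac
        d = np.linalg.norm(w - x[idx], axis=1)
        rank = np.argsort(np.argsort(d))
        w += (eps * np.exp(-rank / lam))[:, None] * (x[idx] - w)

    # Lloyd polishing: snap codebooks to mass-weighted domain centroids
    for _ in range(25):
        d2 = ((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for k in range(n_beads):
            sel = assign == k
            if not sel.any():  # re-seed an empty bead at the farthest point
                far = d2.min(axis=1).argmax()
                w[k] = x[far]
                continue
            w[k] = (m[sel, None] * x[sel]).sum(axis=0) / m[sel].sum()
    d2 = ((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    bead_mass = np.array([m[assign == k].sum() for k in range(n_beads)])

    bonds = set()
    if connectivity is not None:
        for a, b in connectivity:
            ka, kb = int(assign[a]), int(assign[b])
            if ka != kb:
                bonds.add((min(ka, kb), max(ka, kb)))
    elif n_beads > 1:
        near = np.argsort(d2, axis=1)[:, :2]
        for ka, kb in near:
            bonds.add((min(ka, kb), max(ka, kb)))
    bond_list = sorted(bonds)

    nbrs: dict[int, list[int]] = {k: [] for k in range(n_beads)}
    for a, b in bond_list:
        nbrs[a].append(b)
        nbrs[b].append(a)
    angle_list = []
    for j in range(n_beads):
        nb = sorted(nbrs[j])
        for u in range(len(nb)):
            for v in range(u + 1, len(nb)):
                angle_list.append((nb[u], j, nb[v]))

    return CoarseGrainResult(w, bead_mass, bond_list, angle_list, assign)


def synthetic_nanobody_cloud(
    n_points: int = 126, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic stand-in for the averaged nanobody structure.

    A prolate-spheroid point cloud (semi-axes 6.5 x 4.4 x 4.4 sigma, geometric
    mean diameter ~10 sigma, matching the SPH sphere) with one point per
    residue at the mean residue mass.  Purely synthetic: used where the real
    atomistic average structure is not supplied.
    """
    rng = np.random.default_rng(seed)
    semi = np.array([4.4, 4.4, 6.5])
    pts = []
    while len(pts) < n_points:
        p = rng.uniform(-1, 1, size=3)
        if (p**2).sum() <= 1.0:
            pts.append(p * semi)
    coords = np.array(pts)
    masses = np.full(n_points, 110.0)  # mean residue mass, Da
    return coords, masses


# SBCG bonded-term defaults (the fluctuation-matched constants of the original
# scheme require an atomistic trajectory, which is out of scope)
SBCG_BOND_K = 100.0
SBCG_ANGLE_K = 10.0
SBCG_DIHEDRAL_K = 10.0


def build_sbcg_diabody(
    n: int,
    wall_set: str = "repulsive#1",
    nanobody_coords=None,
    nanobody_masses=None,
    n_nb_beads: int = 40,
    seed: int = 0,
    box: tuple[float, float, float] | None = None,
    angle_style: str = "cosine",
    tether_epsilon: float = TETHER_EPSILON,
) -> DiabodySystem:
    """Shape-based diabody: two SBCG nanobodies bridged by an N-bead linker.

    Each nanobody is a flexible bead network (bonds + angles + intra WCA) with
    connector and paratope beads attached at the poles of its long axis; a
    harmonic dihedral restrains each nanobody from rotating about that axis.
    Per Table 1, only the ``s_wall = 0.8`` small-bead wall interaction applies
    to SBCG protein beads.
    """
    if n < 1:
        raise ValueError("linker length must be >= 1")
    if wall_set not in WALL_SETS:
        raise ValueError(f"unknown wall set {wall_set!r}")
    if nanobody_coords is None:
        nanobody_coords, nanobody_masses = synthetic_nanobody_cloud(seed=seed)
    cg = build_sbcg_nanobody(nanobody_coords, nanobody_masses, n_nb_beads, seed=seed)
    radii = assign_bead_radii(cg.masses)
    # orient the long axis along z, centred at the origin
    xyz = cg.positions - cg.positions.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])
    rot = _rotation_to_z(axis)
    xyz = xyz @ rot.T
    proj = xyz[:, 2]
    i_bot, i_top = int(proj.argmin()), int(proj.argmax())

    nb_mass_reduced = cg.masses / PEG_MONOMER_MASS  # linker-monomer mass units

    beads: list[Bead] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    dihedrals: list[DihedralTerm] = []
    pos_rows: list[np.ndarray] = []

    def add_nanobody(tag: str, base_z: float, flip: bool) -> dict:
        """Place one SBCG nanobody; returns index bookkeeping."""
        start = len(beads)
        local = xyz * np.array([1.0, 1.0, -1.0]) if flip else xyz
        lo_local = local[:, 2].min()
        for k in range(cg.n_beads):
            beads.append(
                Bead(start + k, f"{tag}_{k:02d}", 2 * radii[k], nb_mass_reduced[k], "nanobody")
            )
            pos_rows.append(local[k] + np.array([0.0, 0.0, base_z - lo_local]))
        for a, b in cg.bonds:
            r0 = float(np.linalg.norm(local[a] - local[b]))
            bonds.append(BondTerm(start + a, start + b, SBCG_BOND_K, r0))
        for a, j, c in cg.angles:
            v1 = local[a] - local[j]
            v2 = local[c] - local[j]
            th = np.degrees(
                np.arccos(np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
            )
            angles.append(AngleTerm(start + a, start + j, start + c, SBCG_ANGLE_K, float(th)))
        bot = i_top if flip else i_bot
        top = i_bot if flip else i_top
        return {"start": start, "bottom": start + bot, "top": start + top}

    if box is None:
        box = default_box(n)
    cx, cy = box[0] / 2.0, box[1] / 2.0

    tether_s = PARATOPE_DIAMETER / 2  # point-site epitope on the wall plane
    z_p2 = WCA_CUT * tether_s
    p_mass = PARATOPE_DIAMETER**3

    # nbd-2 (tethered): paratope down
    i_p2 = len(beads)
    beads.append(Bead(i_p2, "P2", PARATOPE_DIAMETER, p_mass, "paratope"))
    pos_rows.append(np.array([0.0, 0.0, z_p2]))
    nb2 = add_nanobody("NB2", z_p2 + PARATOPE_DIAMETER / 2 + 0.2, flip=False)
    i_cb2 = len(beads)
    beads.append(Bead(i_cb2, "CB2", CONNECTOR_DIAMETER, 1.0, "connector"))
    z_cb2 = pos_rows[nb2["top"]][2] + radii[i_top] + 0.5
    pos_rows.append(np.array([0.0, 0.0, z_cb2]))

    l_start = len(beads)
    l_beads, l_bonds, l_angles = build_linker(n, angle_style, offset=l_start)
    beads += l_beads
    bonds += l_bonds
    angles += l_angles
    for i in range(n):
        pos_rows.append(np.array([0.0, 0.0, z_cb2 + i + 1.0]))
    i_l1, i_ln = l_start, l_start + n - 1

    i_cb1 = len(beads)
    beads.append(Bead(i_cb1, "CB1", CONNECTOR_DIAMETER, 1.0, "connector"))
    z_cb1 = z_cb2 + n + 1.0
    pos_rows.append(np.array([0.0, 0.0, z_cb1]))
    nb1 = add_nanobody("NB1", z_cb1 + 0.5 + 0.2, flip=False)
    i_p1 = len(beads)
    beads.append(Bead(i_p1, "P1", PARATOPE_DIAMETER, p_mass, "paratope"))
    z_p1 = pos_rows[nb1["top"]][2] + radii[i_top] + PARATOPE_DIAMETER / 2
    pos_rows.append(np.array([0.0, 0.0, z_p1]))

    # attach connectors/paratopes to the pole beads of each nanobody
    def attach(bead_i: int, pole: int) -> None:
        r0 = float(np.linalg.norm(pos_rows[bead_i] - pos_rows[pole]))
        bonds.append(BondTerm(bead_i, pole, SBCG_BOND_K, r0))

    attach(i_p2, nb2["bottom"])
    attach(i_cb2, nb2["top"])
    attach(i_cb1, nb1["bottom"])
    attach(i_p1, nb1["top"])

    # junction straightening restraints, as in the SPH model
    restraint_triples = [(i_ln, i_cb1, nb1["bottom"]), (i_p2, i_cb2, i_l1)]
    if n >= 2:
        restraint_triples += [(i_l1 + 1, i_l1, i_cb2), (i_ln - 1, i_ln, i_cb1)]
    for (a, b, c) in restraint_triples:
        angles.append(AngleTerm(a, b, c, RESTRAINT_BEND_K, 180.0, "harmonic"))

    pos = np.vstack(pos_rows)
    pos[:, 0] += cx
    pos[:, 1] += cy

    # anti-rotation dihedral per nanobody over linker-end -- connector -- two
    # protein beads; the protein beads are chosen off the long axis so the
    # dihedral is well defined (the pole beads are collinear with the
    # junction and would make it degenerate)
    def add_antirotation(lead: int, cb: int, pole: int, start: int) -> None:
        axis = pos[pole] - pos[cb]
        axis /= np.linalg.norm(axis)
        cand = [k for k in range(start, start + cg.n_beads) if k != pole]

        def perp(k: int) -> float:
            v = pos[k] - pos[cb]
            return float(np.linalg.norm(v - (v @ axis) * axis))

        near_pole = sorted(cand, key=lambda k: np.linalg.norm(pos[k] - pos[pole]))[:6]
        nb_a = max(near_pole, key=perp)
        nb_b = max((k for k in cand if k != nb_a), key=perp)
        phi0 = _dihedral_angle(pos[lead], pos[cb], pos[nb_a], pos[nb_b])
        dihedrals.append(
            DihedralTerm(lead, cb, nb_a, nb_b, SBCG_DIHEDRAL_K, float(np.degrees(phi0)))
        )

    add_antirotation(i_ln, i_cb1, nb1["bottom"], nb1["start"])
    add_antirotation(i_l1, i_cb2, nb2["top"], nb2["start"])

    i_epi = len(beads)
    beads.append(Bead(i_epi, "EPI", 1.0, 1.0, "epitope"))
    pos = np.vstack([pos, [cx, cy, 0.0]])

    exclusions = set()
    for t in bonds:
        exclusions.add((min(t.i, t.j), max(t.i, t.j)))
    pairs = build_pair_table(beads, exclusions)

    _, _, attractive, eps_w = WALL_SETS[wall_set]
    wall_lower, wall_upper = [], []
    for b in beads:
        if b.group == "epitope":
            wall_lower.append(WallSpec(1.0, 0.0, 0.0))
            wall_upper.append(WallSpec(1.0, 0.0, 0.0))
            continue
        if attractive and b.group in ("nanobody", "paratope"):
            wall_lower.append(_wall_spec(SMALL_BEAD_S_WALL, True, eps_w))
        else:
            wall_lower.append(_wall_spec(SMALL_BEAD_S_WALL, False, EPS_REPULSIVE))
        wall_upper.append(_wall_spec(SMALL_BEAD_S_WALL, False, EPS_REPULSIVE))

    tether = TetherSpec(
        paratope=i_p2, epitope=i_epi, epsilon=tether_epsilon, s=tether_s, r_cut=2.5 * tether_s
    )
    fixed = np.zeros(len(beads), dtype=bool)
    fixed[i_epi] = True
    return DiabodySystem(
        units=UnitSystem(),
        beads=beads,
        positions=pos,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        rigid_groups=[],
        pairs=pairs,
        wall_lower=wall_lower,
        wall_upper=wall_upper,
        tether=tether,
        box=box,
        linker_length=n,
        fixed=fixed,
        metadata={"model": "SBCG", "wall_set": wall_set, "angle_style": angle_style},
    )


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` to +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
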