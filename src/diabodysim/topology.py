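"""Bead topologies for coarse-grained diabody systems.

A :class:`DiabodySystem` holds everything a sampler needs: beads with radii and
masses, bonded terms (bonds, angles, dihedrals), rigid groups, the pairwise
excluded-volume table, per-bead wall interactions for the two z-walls, and the
tether that pins one paratope to a fixed epitope bead on the lower wall.  The
box is periodic in x and y only.  All quantities are in reduced units (lengths
in sigma, energies in kT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .units import UnitSystem

WCA_CUT = 2.0 ** (1.0 / 6.0)

BeadGroup = ("nanobody", "connector", "paratope", "linker", "epitope")


@dataclass
class Bead:
    id: int
    name: str
    diameter: float
    mass: float
    group: str

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"bead {self.name}: diameter must be positive")
        if self.group not in BeadGroup:
            raise ValueError(f"bead {self.name}: unknown group {self.group!r}")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class BondTerm:
    """Harmonic bond 1/2 k (r - r0)^2."""

    i: int
    j: int
    k: float
    r0: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("bond force constant must be >= 0")


@dataclass
class AngleTerm:
    """Three-body bending term over beads (i, j, k) with vertex j.

    ``style`` selects the functional form:

    * ``"harmonic"`` -- 1/2 k (theta - theta0)^2, theta in radians;
    * ``"cosine"``   -- k (1 + cos theta), the Kratky-Porod bending whose
      quadratic expansion about theta0 = 180 deg is the harmonic form with the
      same coefficient.  Only valid with theta0 = 180 deg.
    """

    i: int
    j: int
    k_idx: int
    k: float
    theta0_deg: float
    style: str = "harmonic"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("angle force constant must be >= 0")
        if not 0.0 <= self.theta0_deg <= 180.0:
            raise ValueError("angle equilibrium must lie in [0, 180] degrees")
        if self.style not in ("harmonic", "cosine"):
            raise ValueError(f"unknown angle style {self.style!r}")
        if self.style == "cosine" and self.theta0_deg != 180.0:
            raise ValueError("cosine bending requires theta0 = 180 deg")


@dataclass
class DihedralTerm:
    """Harmonic dihedral 1/2 k (phi - phi0)^2 with periodic wrapping."""

    i: int
    j: int
    k_idx: int
    l: int
    k: float
    phi0_deg: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("dihedral force constant must be >= 0")


@dataclass
class RigidGroup:
    """Beads moved as a single rigid unit.

    ``reference`` stores body-frame coordinates relative to the group's centre
    of mass; samplers reconstruct lab positions as com + R(q) @ reference so
    internal distances are preserved exactly.
    """

    name: str
    bead_ids: list[int]
    reference: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bead_ids) < 2:
            raise ValueError("a rigid group needs at least two beads")
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (len(self.bead_ids), 3):
            raise ValueError("reference coordinates must be (n_beads, 3)")


@dataclass
class WallSpec:
    """LJ 12-6 wall interaction for one bead: cut at ``r_cut``.

    The cutoff encodes the wall's nature: ``r_cut = 2^(1/6) s_wall`` is purely
    repulsive (WCA), ``r_cut = 2.5 s_wall`` attractive.  ``epsilon`` is in kT.
    """

    s_wall: float
    r_cut: float
    epsilon: float

    @property
    def kind(self) -> str:
        if np.isclose(self.r_cut, WCA_CUT * self.s_wall):
            return "repulsive"
        if np.isclose(self.r_cut, 2.5 * self.s_wall):
            return "attractive"
        return "custom"


@dataclass
class TetherSpec:
    """Deep LJ attraction between the tethered paratope and the epitope bead."""

    paratope: int
    epitope: int
    epsilon: float
    s: float
    r_cut: float


@dataclass
class PairTable:
    """Flat table of non-bonded pair interactions (LJ, cut & shifted)."""

    i: np.ndarray
    j: np.ndarray
    epsilon: np.ndarray
    s: np.ndarray
    r_cut: np.ndarray

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class DiabodySystem:
    units: UnitSystem
    beads: list[Bead]
    positions: np.ndarray
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    dihedrals: list[DihedralTerm]
    rigid_groups: list[RigidGroup]
    pairs: PairTable
    wall_lower: list[WallSpec]
    wall_upper: list[WallSpec]
    tether: TetherSpec | None
    box: tuple[float, float, float]
    linker_length: int
    fixed: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        names = [b.name for b in self.beads]
        if len(set(names)) != len(names):
            raise ValueError("bead names must be unique within a system")
        if self.positions.shape != (len(self.beads), 3):
            raise ValueError("positions must be (n_beads, 3)")
        if len(self.fixed) == 0:
            self.fixed = np.zeros(len(self.beads), dtype=bool)

    # -- lookups ---------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def index(self, name: str) -> int:
        for b in self.beads:
            if b.name == name:
                return b.id
        raise KeyError(f"no bead named {name!r}")

    def bead_group_indices(self, group: str) -> np.ndarray:
        return np.array([b.id for b in self.beads if b.group == group], dtype=np.int64)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads])

    def free_nanobody_indices(self) -> np.ndarray:
        """Beads whose centre of mass defines the collective variables (nbd-1).

        For the rigid-sphere model this is the NB1 rigid group (sphere + CB1 +
        P1); for the shape-based model, all nbd-1 protein beads plus CB1 and P1.
        """
        idx = [b.id for b in self.beads if b.name.startswith("NB1")]
        idx += [self.index("CB1"), self.index("P1")]
        return np.array(sorted(idx), dtype=np.int64)

    def tether_point_xy(self) -> tuple[float, float]:
        if self.tether is None:
            raise ValueError("system has no tether")
        x, y, _ = self.positions[self.tether.epitope]
        return float(x), float(y)

    # -- serialization ---------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "units": asdict(self.units),
            "beads": [asdict(b) for b in self.beads],
            "positions": self.positions.tolist(),
            "bonds": [asdict(t) for t in self.bonds],
            "angles": [asdict(t) for t in self.angles],
            "dihedrals": [asdict(t) for t in self.dihedrals],
            "rigid_groups": [
                {"name": g.name, "bead_ids": g.bead_ids, "reference": g.reference.tolist()}
                for g in self.rigid_groups
            ],
            "pairs": {
                "i": self.pairs.i.tolist(),
                "j": self.pairs.j.tolist(),
                "epsilon": self.pairs.epsilon.tolist(),
                "s": self.pairs.s.tolist(),
                "r_cut": self.pairs.r_cut.tolist(),
            },
            "wall_lower": [asdict(w) for w in self.wall_lower],
            "wall_upper": [asdict(w) for w in self.wall_upper],
            "tether": asdict(self.tether) if self.tether else None,
            "box": list(self.box),
            "linker_length": self.linker_length,
            "fixed": self.fixed.tolist(),
            "metadata": self.metadata,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DiabodySystem":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        pairs = PairTable(
            i=np.array(doc["pairs"]["i"], dtype=np.int64),
            j=np.array(doc["pairs"]["j"], dtype=np.int64),
            epsilon=np.array(doc["pairs"]["epsilon"], dtype=float),
            s=np.array(doc["pairs"]["s"], dtype=float),
            r_cut=np.array(doc["pairs"]["r_cut"], dtype=float),
        )
        return cls(
            units=UnitSystem(**doc["units"]),
            beads=[Bead(**b) for b in doc["beads"]],
            positions=np.array(doc["positions"], dtype=float),
            bonds=[BondTerm(**t) for t in doc["bonds"]],
            angles=[AngleTerm(**t) for t in doc["angles"]],
            dihedrals=[DihedralTerm(**t) for t in doc["dihedrals"]],
            rigid_groups=[
                RigidGroup(g["name"], list(g["bead_ids"]), np.array(g["reference"]))
                for g in doc["rigid_groups"]
            ],
            pairs=pairs,
            wall_lower=[WallSpec(**w) for w in doc["wall_lower"]],
            wall_upper=[WallSpec(**w) for w in doc["wall_upper"]],
            tether=TetherSpec(**doc["tether"]) if doc["tether"] else None,
            box=tuple(doc["box"]),
            linker_length=int(doc["linker_length"]),
            fixed=np.array(doc["fixed"], dtype=bool),
            metadata=doc.get("metadata", {}),
        )


def build_pair_table(
    beads: Sequence[Bead],
    exclusions: set[tuple[int, int]],
    epsilon: float = 1.0 / 3.0,
) -> PairTable:
    """All-pairs WCA table from bead radii, minus the supplied exclusions.

    ``s_ij`` is the sum of the two bead radii; every pair is purely repulsive
    (cut at 2^(1/6) s_ij).  Epitope beads only interact through the tether.
    """
    ii, jj, ss = [], [], []
    n = len(beads)
    for a in range(n):
        if beads[a].group == "epitope":
            continue
        for b in range(a + 1, n):
            if beads[b].group == "epitope":
                continue
            if (a, b) in exclusions:
                continue
            ii.append(a)
            jj.append(b)
            ss.append(beads[a].radius + beads[b].radius)
    s = np.array(ss, dtype=float)
    return PairTable(
        i=np.array(ii, dtype=np.int64),
        j=np.array(jj, dtype=np.int64),
        epsilon=np.full(len(s), epsilon, dtype=float),
        s=s,
        r_cut=WCA_CUT * s,
    )
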