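"""File formats: XYZ and HDF5 trajectories, CSV observable tables with header
metadata, PDB coordinate input for the coarse-grainer, and a LAMMPS data-file
export of built topologies (atom_style full dialect).

All files are written in reduced units.  The CSV dialect is comma-separated
with '#'-prefixed header metadata lines.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .engine import Trajectory
from .topology import DiabodySystem


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def write_xyz(trajectory: Trajectory, path, precision: int = 6) -> None:
    """Multi-frame XYZ with bead names preserved in the atom column."""
    fmt = f"{{}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{len(trajectory.names)}\n")
            fh.write(
                f"frame={f} interval={trajectory.frame_interval} "
                f"box={trajectory.box[0]},{trajectory.box[1]},{trajectory.box[2]}\n"
            )
            for name, row in zip(trajectory.names, trajectory.frames[f]):
                fh.write(fmt.format(name, row[0], row[1], row[2]))


def read_xyz(path, frame_interval: float = 1.0) -> Trajectory:
    """Read a (possibly foreign) XYZ file; extra columns are ignored with a
    warning; a zero-frame file raises a parse error."""
    frames, names = [], None
    box = (0.0, 0.0, 0.0)
    warned = False
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].split()[0])
        except ValueError:
            raise TrajectoryParseError("expected an atom count", i + 1) from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if "interval=" in comment:
            try:
                frame_interval = float(comment.split("interval=")[1].split()[0])
            except ValueError:
                pass
        if "box=" in comment:
            try:
                box = tuple(float(x) for x in comment.split("box=")[1].split()[0].split(","))
            except ValueError:
                pass
        rows, row_names = [], []
        for k in range(nat):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise TrajectoryParseError("truncated frame", lineno + 1)
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise TrajectoryParseError("expected 'name x y z'", lineno + 1)
            if len(parts) > 4 and not warned:
                warnings.warn("extra columns in XYZ input ignored", stacklevel=2)
                warned = True
            try:
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise TrajectoryParseError("non-numeric coordinate", lineno + 1) from None
            row_names.append(parts[0])
        if names is None:
            names = row_names
        frames.append(rows)
        i += 2 + nat
    if not frames:
        raise TrajectoryParseError("file contains no frames")
    return Trajectory(
        np.array(frames, dtype=float), names, frame_interval, box,
        provenance={"source": str(path), "format": "xyz"},
    )


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------


def write_hdf5(trajectory: Trajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=trajectory.frames)
        fh.create_dataset(
            "names", data=np.array(trajectory.names, dtype=h5py.string_dtype())
        )
        fh.attrs["frame_interval"] = trajectory.frame_interval
        fh.attrs["box"] = trajectory.box
        fh.attrs["provenance"] = json.dumps(trajectory.provenance)
        if trajectory.energies is not None:
            fh.create_dataset("energies", data=trajectory.energies)


def read_hdf5(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        return Trajectory(
            frames=fh["frames"][...],
            names=[s.decode() if isinstance(s, bytes) else s for s in fh["names"][...]],
            frame_interval=float(fh.attrs["frame_interval"]),
            box=tuple(fh.attrs["box"]),
            provenance=json.loads(fh.attrs.get("provenance", "{}")),
            energies=fh["energies"][...] if "energies" in fh else None,
        )


# ---------------------------------------------------------------------------
# CSV observable tables
# ---------------------------------------------------------------------------


def write_series_csv(path, columns: dict, metadata: dict | None = None) -> None:
    """Comma-separated columns with '#'-prefixed metadata header lines."""
    keys = list(columns)
    arrays = [np.asarray(columns[k]) for k in keys]
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write(",".join(keys) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(f"{x:.10g}" for x in row) + "\n")


def read_series_csv(path) -> tuple[dict, dict]:
    """Returns (columns, metadata) from a '#'-headed CSV table."""
    metadata: dict = {}
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    metadata[k.strip()] = v.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            rows.append([float(x) for x in line.split(",")])
    if header is None:
        raise ValueError(f"{path}: no data")
    data = np.array(rows, dtype=float)
    return {h: data[:, k] for k, h in enumerate(header)}, metadata


def read_height_series(path) -> tuple[np.ndarray, float]:
    """Two-column (time, z) table -> (z series, frame interval).

    Accepts the package CSV dialect or plain whitespace/comma-delimited text,
    so height series from external MD engines can be analyzed directly.
    """
    try:
        cols, _ = read_series_csv(path)
        names = list(cols)
        t, z = cols[names[0]], cols[names[1]]
    except (ValueError, IndexError):
        data = np.loadtxt(path)
        if data.ndim == 1:
            return data, 1.0
        t, z = data[:, 0], data[:, 1]
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return np.asarray(z, dtype=float), dt


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------


def read_pdb_coords(path, ca_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (angstrom) and masses (Da) from a PDB file.

    With ``ca_only`` one point per residue at the CA position is returned,
    carrying the summed mass of the residue's atoms present in the file;
    otherwise every heavy atom with its element mass.  Used as SBCG input.
    """
    import biotite.structure.io.pdb as pdb
    import biotite.structure as struc

    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    structure = structure[~struc.filter_solvent(structure)]
    if ca_only:
        res_masses = {}
        for res_id, res_name in zip(structure.res_id, structure.res_name):
            res_masses.setdefault(res_id, 0.0)
        for at in range(len(structure)):
            m = struc.info.mass(structure.element[at].capitalize())
            res_masses[structure.res_id[at]] += 0.0 if m is None else m
        ca = structure[structure.atom_name == "CA"]
        coords = ca.coord
        masses = np.array([res_masses.get(r, 110.0) for r in ca.res_id])
    else:
        sel = structure.element != "H"
        coords = structure.coord[sel]
        masses = np.array(
            [struc.info.mass(e.capitalize()) or 12.0 for e in structure.element[sel]]
        )
    return np.asarray(coords, dtype=float), masses


# ---------------------------------------------------------------------------
# LAMMPS export
# ---------------------------------------------------------------------------


def write_lammps_data(system: DiabodySystem, path) -> None:
    """LAMMPS data file (atom_style full) of a built topology.

    Bead types are grouped by (diameter, group); bond/angle/dihedral
    coefficients are not emitted (pair and bonded styles differ per term
    here), only the topology and geometry for cross-validation.
    """
    type_key = [(b.diameter, b.group) for b in system.beads]
    types = sorted(set(type_key))
    t_of = {k: i + 1 for i, k in enumerate(types)}
    lx, ly, lz = system.box
    with open(path, "w") as fh:
        fh.write("LAMMPS data file: coarse-grained diabody (reduced units)\n\n")
        fh.write(f"{system.n_beads} atoms\n")
        fh.write(f"{len(system.bonds)} bonds\n")
        fh.write(f"{len(system.angles)} angles\n")
        fh.write(f"{len(system.dihedrals)} dihedrals\n\n")
        fh.write(f"{len(types)} atom types\n")
        fh.write(f"{max(len(system.bonds), 1)} bond types\n")
        fh.write(f"{max(len(system.angles), 1)} angle types\n")
        if system.dihedrals:
            fh.write(f"{len(system.dihedrals)} dihedral types\n")
        fh.write(f"\n0.0 {lx} xlo xhi\n0.0 {ly} ylo yhi\n0.0 {lz} zlo zhi\n")
        fh.write("\nMasses\n\n")
        mass_of = {}
        for b in system.beads:
            mass_of.setdefault(t_of[(b.diameter, b.group)], b.mass)
        for t in sorted(mass_of):
            fh.write(f"{t} {mass_of[t]}\n")
        fh.write("\nAtoms # full\n\n")
        for b, r in zip(system.beads, system.positions):
            fh.write(
                f"{b.id + 1} 1 {t_of[(b.diameter, b.group)]} 0.0 "
                f"{r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n"
            )
        if system.bonds:
            fh.write("\nBonds\n\n")
            for k, t in enumerate(system.bonds):
                fh.write(f"{k + 1} {k + 1} {t.i + 1} {t.j + 1}\n")
        if system.angles:
            fh.write("\nAngles\n\n")
            for k, t in enumerate(system.angles):
                fh.write(f"{k + 1} {k + 1} {t.i + 1} {t.j + 1} {t.k_idx + 1}\n")
        if system.dihedrals:
            fh.write("\nDihedrals\n\n")
            for k, t in enumerate(system.dihedrals):
                fh.write(
                    f"{k + 1} {k + 1} {t.i + 1} {t.j + 1} {t.k_idx + 1} {t.l + 1}\n"
                )


def write_provenance(path, payload: dict) -> None:
    """JSON provenance sidecar (config, seed, package version)."""
    from . import __version__

    doc = dict(payload)
    doc.setdefault("package_version", __version__)
    Path(path).write_text(json.dumps(doc, indent=1, default=str))
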