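"""Plain-text readers/writers: LAMMPS data files, LAMMPS dump, XYZ, provenance.

Data files use ``atom_style full`` (atom-ID molecule-ID type charge x y z)
with a Bonds section; dump files carry ``id type q x y z``.  All writers
emit a provenance JSON next to the main file when asked.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .errors import ConfigurationError
from .model import SPECIES_NAMES, SystemState


def write_lammps_data(state: SystemState, path, provenance: dict | None = None):
    """Write an atom_style full data file (+ optional provenance JSON)."""
    path = Path(path)
    n = state.n
    n_types = int(state.species.max()) if n else 1
    lines = [
        "LAMMPS data file generated by gelion",
        "",
        f"{n} atoms",
        f"{len(state.bonds)} bonds",
        "",
        f"{n_types} atom types",
        f"{1 if len(state.bonds) else 0} bond types",
        "",
        f"0.0 {state.box_length:.10g} xlo xhi",
        f"0.0 {state.box_length:.10g} ylo yhi",
        f"0.0 {state.box_length:.10g} zlo zhi",
        "",
        "Masses",
        "",
    ]
    lines += [f"{t} 1.0" for t in range(1, n_types + 1)]
    lines += ["", "Atoms # full", ""]
    for i in range(n):
        x, y, z = state.positions[i]
        lines.append(
            f"{i + 1} 1 {state.species[i]} {state.charge[i]:.1f} "
            f"{x:.10g} {y:.10g} {z:.10g}")
    if len(state.bonds):
        lines += ["", "Bonds", ""]
        for b, (p, q) in enumerate(state.bonds, start=1):
            lines.append(f"{b} 1 {p + 1} {q + 1}")
    path.write_text("\n".join(lines) + "\n")
    if provenance is not None:
        write_provenance(path.with_suffix(".provenance.json"),
                         dict(provenance, metadata=_clean(state.metadata)))


def read_lammps_data(path) -> SystemState:
    """Read back a data file written by :func:`write_lammps_data`."""
    text = Path(path).read_text().splitlines()
    n_atoms = n_bonds = None
    L = None
    section = None
    atoms = {}
    bonds = []
    for raw in text:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if line.endswith("atoms"):
            n_atoms = int(line.split()[0])
            continue
        if line.endswith("bonds"):
            n_bonds = int(line.split()[0])
            continue
        if "xlo xhi" in line:
            lo, hi = map(float, line.split()[:2])
            L = hi - lo
            continue
        if "ylo yhi" in line or "zlo zhi" in line or line.endswith("types"):
            continue
        if line in ("Masses", "Atoms", "Bonds", "Velocities"):
            section = line
            continue
        if section == "Atoms":
            parts = line.split()
            aid = int(parts[0])
            atoms[aid] = (int(parts[2]), float(parts[3]),
                          float(parts[4]), float(parts[5]), float(parts[6]))
        elif section == "Bonds":
            parts = line.split()
            bonds.append((int(parts[2]) - 1, int(parts[3]) - 1))
    if n_atoms is None or L is None:
        raise ConfigurationError(f"{path}: not a recognisable LAMMPS data file")
    order = sorted(atoms)
    species = np.array([atoms[a][0] for a in order], dtype=np.int64)
    charge = np.array([int(round(atoms[a][1])) for a in order], dtype=np.int64)
    pos = np.array([atoms[a][2:5] for a in order], dtype=float)
    return SystemState(
        positions=pos,
        velocities=np.zeros_like(pos),
        charge=charge,
        species=species,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        box_length=L,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_dump(traj: Trajectory, path):
    """LAMMPS dump with columns id type q x y z, one block per frame."""
    path = Path(path)
    L = traj.box_length
    with path.open("w") as fh:
        for fidx in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{fidx}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {L:.10g}\n")
            fh.write("ITEM: ATOMS id type q x y z\n")
            pos = traj.positions[fidx]
            for i in range(traj.n):
                fh.write(f"{i + 1} {traj.species[i]} {traj.charge[i]:.1f} "
                         f"{pos[i, 0]:.7g} {pos[i, 1]:.7g} {pos[i, 2]:.7g}\n")


def read_dump(path, bonds: np.ndarray | None = None) -> Trajectory:
    """Read an ``id type q x y z`` LAMMPS dump into a Trajectory."""
    frames, times = [], []
    species = charge = None
    L = None
    with Path(path).open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ConfigurationError(f"{path}: malformed dump near line {i}")
        t = float(lines[i + 1])
        n = int(lines[i + 3])
        lo, hi = map(float, lines[i + 5].split()[:2])
        L = hi - lo
        header = lines[i + 8].split()[2:]
        col = {name: c for c, name in enumerate(header)}
        for key in ("id", "type", "x", "y", "z"):
            if key not in col:
                raise ConfigurationError(f"{path}: dump missing column {key!r}")
        block = lines[i + 9:i + 9 + n]
        data = np.array([row.split() for row in block], dtype=float)
        order = np.argsort(data[:, col["id"]])
        data = data[order]
        if species is None:
            species = data[:, col["type"]].astype(np.int64)
            charge = (data[:, col["q"]].astype(np.int64)
                      if "q" in col else np.zeros(n, dtype=np.int64))
        frames.append(data[:, [col["x"], col["y"], col["z"]]])
        times.append(t)
        i += 9 + n
    if not frames:
        raise ConfigurationError(f"{path}: empty dump")
    return Trajectory(
        positions=np.asarray(frames),
        times=np.asarray(times),
        species=species,
        charge=charge,
        bonds=(np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
               if bonds is not None else np.empty((0, 2), dtype=np.int64)),
        box_length=L,
    )


def write_xyz(traj: Trajectory, path):
    """Minimal XYZ: species names as element labels."""
    with Path(path).open("w") as fh:
        for fidx in range(traj.n_frames):
            fh.write(f"{traj.n}\n")
            fh.write(f'frame={fidx} box={traj.box_length:.10g}\n')
            pos = traj.positions[fidx]
            for i in range(traj.n):
                name = SPECIES_NAMES.get(int(traj.species[i]), "X")
                fh.write(f"{name} {pos[i, 0]:.7g} {pos[i, 1]:.7g} {pos[i, 2]:.7g}\n")


def read_xyz(path, box_length: float | None = None) -> Trajectory:
    with Path(path).open() as fh:
        lines = fh.read().splitlines()
    frames, species = [], None
    L = box_length
    i = 0
    from .model import SPECIES_CODES
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        if "box=" in comment:
            L = float(comment.split("box=")[1].split()[0])
        block = lines[i + 2:i + 2 + n]
        if species is None:
            species = np.array(
                [SPECIES_CODES.get(row.split()[0], 0) for row in block],
                dtype=np.int64)
        frames.append(np.array([row.split()[1:4] for row in block], dtype=float))
        i += 2 + n
    if L is None:
        raise ConfigurationError("box length unknown: pass box_length")
    return Trajectory(
        positions=np.asarray(frames),
        times=np.arange(len(frames), dtype=float),
        species=species,
        charge=np.zeros(len(species), dtype=np.int64),
        bonds=np.empty((0, 2), dtype=np.int64),
        box_length=float(L),
    )


def write_thermo(thermo: pd.DataFrame, path):
    thermo.to_csv(path, index=False)


def write_provenance(path, payload: dict):
    Path(path).write_text(json.dumps(_clean(payload), indent=2, sort_keys=True) + "\n")


def _clean(obj):
    """Make metadata JSON-serialisable."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
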