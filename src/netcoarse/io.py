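"""Trajectory and field readers/writers.

Text formats only: extended XYZ (species, positions, velocities, with
Lattice and Time in the comment line) and LAMMPS dump text
(id type x y z vx vy vz, plus optional image flags ix iy iz).  Orthogonal
(cubic/square) boxes only; triclinic boxes are rejected.  Fields go out as
flat binary arrays with a JSON sidecar recording shape, spacing and time.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fields import ScalarField
from .state import ParticleState, Trajectory


class TrajectoryParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# extended XYZ


def write_extxyz(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for f in traj.frames:
            L = f.box_length
            d = f.dims
            lat = np.zeros((3, 3))
            for i in range(3):
                lat[i, i] = L if i < d else 1.0
            lat_str = " ".join(f"{x:.10g}" for x in lat.ravel())
            fh.write(f"{f.n}\n")
            fh.write(f'Lattice="{lat_str}" '
                     f'Properties=species:S:1:pos:R:3:velo:R:3 '
                     f"Time={f.time:.10g}\n")
            for i in range(f.n):
                p = np.zeros(3)
                v = np.zeros(3)
                p[:d] = f.positions[i]
                v[:d] = f.velocities[i]
                fh.write(f"T{f.species[i]} "
                         f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                         f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")


def read_extxyz(path) -> Trajectory:
    frames = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                break
            if not header.strip():
                continue
            try:
                n = int(header)
            except ValueError:
                raise TrajectoryParseError(
                    f"{path}:{lineno}: expected atom count, got {header!r}")
            comment = fh.readline()
            lineno += 1
            m = re.search(r'Lattice="([^"]+)"', comment)
            if not m:
                raise TrajectoryParseError(
                    f"{path}:{lineno}: missing Lattice in comment line")
            lat = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
            off_diag = lat - np.diag(np.diag(lat))
            if np.abs(off_diag).max() > 1e-12:
                raise TrajectoryParseError(
                    f"{path}:{lineno}: triclinic boxes are not supported")
            tm = re.search(r"Time=([-\d.eE+]+)", comment)
            time = float(tm.group(1)) if tm else float(len(frames))
            dims = 2 if abs(lat[2, 2] - 1.0) < 1e-12 and lat[0, 0] != 1.0 and \
                np.isclose(lat[1, 1], lat[0, 0]) and not np.isclose(lat[2, 2], lat[0, 0]) else 3
            L = lat[0, 0]
            species = np.empty(n, np.int64)
            pos = np.empty((n, 3))
            vel = np.zeros((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) < 4:
                    raise TrajectoryParseError(
                        f"{path}:{lineno}: truncated atom line")
                species[i] = int(parts[0].lstrip("T")) if parts[0].lstrip("T").isdigit() else 0
                pos[i] = [float(x) for x in parts[1:4]]
                if len(parts) >= 7:
                    vel[i] = [float(x) for x in parts[4:7]]
            frames.append(ParticleState(pos[:, :dims], vel[:, :dims], species,
                                        L, time=time))
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# LAMMPS dump text


def write_lammps_dump(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for f in traj.frames:
            d = f.dims
            L = f.box_length
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{f.time:.10g}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{f.n}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for i in range(3):
                hi = L if i < d else 1.0
                fh.write(f"0 {hi:.10g}\n")
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            for i in range(f.n):
                p = np.zeros(3)
                v = np.zeros(3)
                p[:d] = f.positions[i]
                v[:d] = f.velocities[i]
                fh.write(f"{i + 1} {f.species[i] + 1} "
                         f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                         f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")


def read_lammps_dump(path) -> Trajectory:
    """Reads text dumps with columns id type x y z [vx vy vz] [ix iy iz].

    Image flags, if present, are used to unwrap positions: the returned
    frame positions are wrapped, but unwrapped coordinates are recovered
    exactly by Trajectory.unwrapped_positions when crossings between
    frames are below L/2, or stored in frame metadata otherwise.
    """
    frames = []
    has_velocities = True
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            if not lines[i].strip():
                i += 1
                continue
            raise TrajectoryParseError(f"{path}:{i + 1}: expected ITEM: TIMESTEP")
        time = float(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise TrajectoryParseError(f"{path}:{i + 3}: expected NUMBER OF ATOMS")
        n = int(lines[i + 3])
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryParseError(f"{path}:{i + 5}: expected BOX BOUNDS")
        if "xy" in lines[i + 4]:
            raise TrajectoryParseError(
                f"{path}:{i + 5}: triclinic boxes are not supported")
        bounds = [lines[i + 5 + k].split() for k in range(3)]
        los = [float(b[0]) for b in bounds]
        his = [float(b[1]) for b in bounds]
        sizes = [hi - lo for lo, hi in zip(los, his)]
        dims = 2 if abs(sizes[2] - 1.0) < 1e-12 and not np.isclose(sizes[0], 1.0) \
            and np.isclose(sizes[0], sizes[1]) and not np.isclose(sizes[2], sizes[0]) else 3
        L = sizes[0]
        header = lines[i + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise TrajectoryParseError(f"{path}:{i + 9}: expected ITEM: ATOMS")
        cols = header.split()[2:]
        col = {c: j for j, c in enumerate(cols)}
        for req in ("id", "x", "y"):
            if req not in col:
                raise TrajectoryParseError(
                    f"{path}:{i + 9}: missing column {req!r}")
        has_vel = "vx" in col
        has_velocities = has_velocities and has_vel
        has_img = "ix" in col
        pos = np.empty((n, 3))
        vel = np.zeros((n, 3))
        img = np.zeros((n, 3), np.int64)
        species = np.zeros(n, np.int64)
        ids = np.empty(n, np.int64)
        for a in range(n):
            parts = lines[i + 9 + a].split()
            ids[a] = int(parts[col["id"]])
            if "type" in col:
                species[a] = int(parts[col["type"]]) - 1
            pos[a] = [float(parts[col["x"]]), float(parts[col["y"]]),
                      float(parts[col["z"]]) if "z" in col else 0.0]
            if has_vel:
                vel[a] = [float(parts[col["vx"]]), float(parts[col["vy"]]),
                          float(parts[col["vz"]]) if "vz" in col else 0.0]
            if has_img:
                img[a] = [int(parts[col["ix"]]), int(parts[col["iy"]]),
                          int(parts[col["iz"]]) if "iz" in col else 0]
        order = np.argsort(ids)
        pos, vel, img, species = pos[order], vel[order], img[order], species[order]
        pos = pos - np.array(los)
        st = ParticleState(pos[:, :dims] % L, vel[:, :dims], species, L,
                           time=time)
        frames.append(st)
        if has_img:
            unwrapped = pos[:, :dims] + img[:, :dims] * L
            st.unwrapped = unwrapped  # type: ignore[attr-defined]
        i += 9 + n
    traj = Trajectory(frames=frames)
    traj.metadata["has_velocities"] = has_velocities
    return traj


def read_trajectory(path, fmt: Optional[str] = None) -> Trajectory:
    """Dispatch on format: 'extxyz' | 'lammps' (guessed from content)."""
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "lammps" if first.startswith("ITEM:") else "extxyz"
    if fmt == "extxyz":
        return read_extxyz(path)
    if fmt == "lammps":
        return read_lammps_dump(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# thermo log and fields


def write_thermo_csv(path, traj: Trajectory) -> None:
    df = pd.DataFrame(traj.thermo,
                      columns=["time", "T_kin", "E_pot", "pressure"])
    df.to_csv(path, index=False)


def read_thermo_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_field(path_prefix, field: ScalarField) -> None:
    """Flat binary (.bin, float64 C-order) plus JSON sidecar (.json)."""
    prefix = Path(path_prefix)
    field.values.astype(np.float64).tofile(prefix.with_suffix(".bin"))
    sidecar = {"shape": list(field.values.shape),
               "grid_spacing": field.grid_spacing,
               "time": field.time, "dtype": "float64", "order": "C",
               "meta": {k: v for k, v in field.meta.items()
                        if isinstance(v, (str, int, float, bool))}}
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_field(path_prefix) -> ScalarField:
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    values = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float64)
    values = values.reshape(sidecar["shape"])
    return ScalarField(values, sidecar["grid_spacing"], time=sidecar["time"],
                       meta=sidecar.get("meta", {}))
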