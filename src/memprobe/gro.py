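"""Minimal multi-frame GRO reader/writer.

A frame is a title line (carrying ``t= <time in ps>`` when available), an atom
count, fixed-width atom lines and a box line; trajectories are frames
concatenated in one file.  Coordinates and box lengths are in nm.  Only the
first three box components (rectangular box) are used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Frame", "read_gro", "write_gro"]

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


@dataclass
class Frame:
    """One trajectory frame: coordinates (N, 3) nm, box lengths (3,) nm, time in ns."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)[:3]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box components must be positive")


def read_gro(path) -> tuple[pd.DataFrame, list[Frame]]:
    """Read a (multi-frame) GRO file.

    Returns the atom table (resid, resname, name) from the first frame and a
    list of frames.  All frames must have the same atom count.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    atoms: pd.DataFrame | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed GRO atom count near line {i + 2}") from exc
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms or i + 2 + natoms >= len(lines) + 1:
            raise ValueError(f"truncated GRO frame starting at line {i + 1}")
        coords = np.empty((natoms, 3))
        recs = []
        for j, ln in enumerate(atom_lines):
            try:
                resid = int(ln[0:5])
                resname = ln[5:10].strip()
                name = ln[10:15].strip()
                coords[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except ValueError as exc:
                raise ValueError(f"malformed GRO atom line {i + 3 + j}: {ln!r}") from exc
            recs.append((resid, resname, name))
        box_line = lines[i + 2 + natoms].split()
        box = np.array([float(x) for x in box_line[:3]])
        m = _TIME_RE.search(title)
        t_ns = float(m.group(1)) / 1000.0 if m else float(len(frames))
        frames.append(Frame(coords, box, time=t_ns))
        if atoms is None:
            atoms = pd.DataFrame(recs, columns=["resid", "resname", "name"])
        elif natoms != len(atoms):
            raise ValueError("frames differ in atom count")
        i += 2 + natoms + 1
    if atoms is None:
        raise ValueError(f"no frames found in {path}")
    return atoms, frames


def write_gro(path, atoms: pd.DataFrame, frames: list[Frame], system: str = "memprobe") -> None:
    """Write frames as concatenated GRO; time stamps go on the title line in ps."""
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{system} t= {fr.time * 1000.0:.3f}\n")
            fh.write(f"{len(atoms):5d}\n")
            for j, (resid, resname, name) in enumerate(
                zip(atoms["resid"], atoms["resname"], atoms["name"])
            ):
                x, y, z = fr.coords[j]
                fh.write(
                    f"{int(resid) % 100000:5d}{resname:<5.5s}{name:>5.5s}"
                    f"{(j + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")
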