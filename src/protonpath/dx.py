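"""Minimal OpenDX scalar-grid I/O for potential and map dumps.

Writes the regular-grid subset of OpenDX understood by PyMOL, VMD and APBS
tooling (positions by origin+deltas, three-token data lines).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .pb import GridSpec, PotentialField

__all__ = ["write_dx", "read_dx"]


def write_dx(field: PotentialField, path, comment: str = "protonpath scalar field") -> None:
    grid = field.grid
    nx, ny, nz = grid.dims
    h = grid.spacing
    ox, oy, oz = grid.origin
    vals = np.asarray(field.phi, dtype=float).ravel(order="C")
    lines = [
        f"# {comment}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6e} {oy:.6e} {oz:.6e}",
        f"delta {h:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {h:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {h:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {vals.size} data follows",
    ]
    for i in range(0, vals.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> PotentialField:
    """Read a regular-grid OpenDX scalar file written by :func:`write_dx`."""
    dims = None
    origin = None
    deltas = []
    data = []
    n_expected = None
    with open(path) as fh:
        for line in fh:
            t = line.split()
            if not t or t[0].startswith("#"):
                continue
            if t[0] == "object" and "gridpositions" in line:
                dims = tuple(int(v) for v in t[-3:])
            elif t[0] == "origin":
                origin = np.array([float(v) for v in t[1:4]])
            elif t[0] == "delta":
                deltas.append([float(v) for v in t[1:4]])
            elif t[0] == "object" and "data follows" in line:
                n_expected = int(t[-3])
            elif t[0] == "attribute" or (t[0] == "object" and "class field" in line):
                continue
            elif n_expected is not None and len(data) < n_expected:
                data.extend(float(v) for v in t)
    if dims is None or origin is None or len(deltas) != 3 or n_expected is None:
        raise ValueError(f"{path} is not a regular-grid OpenDX scalar file")
    d = np.array(deltas)
    spacing = float(d[0, 0])
    if not (np.allclose(np.diag(d), spacing) and np.allclose(d - np.diag(np.diag(d)), 0)):
        raise ValueError("only axis-aligned uniform-spacing OpenDX grids are supported")
    phi = np.array(data, dtype=float).reshape(dims, order="C")
    return PotentialField(grid=GridSpec(origin=origin, spacing=spacing, dims=dims), phi=phi)
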