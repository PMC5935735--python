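"""Molecular structures, protonation-state charge perturbations, and frame ensembles.

Units are fixed package-wide: coordinates in Å, charges in elementary
charges (e), radii in Å, energies in kcal/mol.  There is deliberately no
unit configuration; every module in :mod:`protonpath` assumes this system.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "TitratableSite",
    "FrameSet",
    "PqrParseError",
    "read_pqr",
    "write_pqr",
    "read_frames",
    "apply_charge_state",
    "distance_series",
]


class PqrParseError(ValueError):
    """Raised when a PQR record cannot be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class Atom:
    """A point particle with partial charge and hard-sphere radius.

    Parameters
    ----------
    index : int
        0-based ordinal within the parent :class:`Structure`.
    name : str
        Atom label, e.g. ``"OH"``.
    residue_label : str
        Residue label, e.g. ``"TYR"``.
    position : (3,) ndarray
        Cartesian coordinates, Å.
    charge : float
        Partial charge, e.
    radius : float
        Dielectric/ion-exclusion radius, Å.  Must be non-negative.
    """

    index: int
    name: str
    residue_label: str
    position: np.ndarray
    charge: float
    radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        object.__setattr__(self, "position", pos)
        if not np.isfinite(self.charge):
            raise ValueError("charge must be finite")
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")

    def with_charge(self, charge: float) -> "Atom":
        return dataclasses.replace(self, charge=float(charge))


@dataclass
class Structure:
    """An ordered collection of atoms; the solute of a continuum-electrostatics solve."""

    atoms: List[Atom]
    title: str = ""

    def __post_init__(self):
        for k, atom in enumerate(self.atoms):
            if atom.index != k:
                raise ValueError(
                    f"atom indices must be contiguous from 0; atom {k} has index {atom.index}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of coordinates, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def net_charge(self) -> float:
        return float(np.sum(self.charges))

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Return a copy with new coordinates (same charges/radii/topology)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self), 3):
            raise ValueError(
                f"expected positions of shape ({len(self)}, 3), got {positions.shape}"
            )
        atoms = [
            dataclasses.replace(a, position=positions[k]) for k, a in enumerate(self.atoms)
        ]
        return Structure(atoms=atoms, title=self.title)


@dataclass
class TitratableSite:
    """A protonation-state charge perturbation over a subset of atoms.

    ``delta_q[k]`` is the charge on atom ``atom_indices[k]`` in the
    protonated state minus its charge in the deprotonated state; the sum
    must equal +1 (one proton charge) to 1e-6.  ``model_pka`` is the pKa of
    the corresponding model compound free in solvent.
    """

    label: str
    atom_indices: List[int]
    delta_q: List[float]
    model_pka: float = 7.0

    def __post_init__(self):
        if len(self.atom_indices) != len(self.delta_q):
            raise ValueError("atom_indices and delta_q must have equal length")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("atom_indices must be unique")
        total = float(np.sum(self.delta_q))
        if abs(total - 1.0) >= 1e-6:
            raise ValueError(
                f"sum of delta_q must be +1 (a protonation adds one proton charge); got {total}"
            )


@dataclass
class FrameSet:
    """A coordinate ensemble: every frame shares one atom count and topology.

    Frames carry coordinates only; charges and radii always come from a
    template :class:`Structure` (the fixed-topology snapshot convention).
    """

    n_atoms: int
    frames: List[np.ndarray]

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("FrameSet requires at least one frame")
        coerced = []
        for k, fr in enumerate(self.frames):
            fr = np.asarray(fr, dtype=float)
            if fr.shape != (self.n_atoms, 3):
                raise ValueError(
                    f"frame {k} has shape {fr.shape}, expected ({self.n_atoms}, 3)"
                )
            coerced.append(fr)
        self.frames = coerced

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# PQR I/O
#
# Dialect: whitespace-delimited (the common PDB2PQR output layout):
#   ATOM serial name resname [chain] resnum x y z charge radius
# The chain column is optional on read; the writer never emits it.
# ---------------------------------------------------------------------------


def _parse_pqr_record(fields: Sequence[str], lineno: int) -> tuple:
    # With chain id there are 11 fields, without it 10.
    if len(fields) == 11:
        name, resname, resnum = fields[2], fields[3], fields[5]
        numeric = fields[6:]
    elif len(fields) == 10:
        name, resname, resnum = fields[2], fields[3], fields[4]
        numeric = fields[5:]
    else:
        raise PqrParseError(
            lineno, f"expected 10 or 11 whitespace-delimited fields, got {len(fields)}"
        )
    try:
        x, y, z, q, r = (float(v) for v in numeric)
    except ValueError:
        raise PqrParseError(lineno, f"non-numeric coordinate/charge/radius field in {numeric}")
    return name, resname, x, y, z, q, r


def read_pqr(path) -> Structure:
    """Read a whitespace-delimited PQR file into a :class:`Structure`.

    Atoms are kept in file order and re-indexed from 0; file serial numbers
    are not trusted for identity.  Malformed records raise
    :class:`PqrParseError` naming the offending line.
    """
    path = Path(path)
    atoms: List[Atom] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec:
                continue
            tag = rec[0].upper()
            if tag in ("REMARK", "TER", "END", "ENDMDL", "MODEL"):
                if tag == "REMARK" and not title:
                    title = line[6:].strip()
                continue
            if tag not in ("ATOM", "HETATM"):
                continue
            name, resname, x, y, z, q, r = _parse_pqr_record(rec, lineno)
            if r < 0:
                raise PqrParseError(lineno, f"negative radius {r}")
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=name,
                    residue_label=resname,
                    position=np.array([x, y, z]),
                    charge=q,
                    radius=r,
                )
            )
    if not atoms:
        raise PqrParseError(0, f"no ATOM/HETATM records found in {path}")
    return Structure(atoms=atoms, title=title)


def write_pqr(structure: Structure, path) -> None:
    """Write ``structure`` as whitespace-delimited PQR (re-readable by :func:`read_pqr`)."""
    if len(structure) == 0:
        raise ValueError("cannot write an empty structure")
    path = Path(path)
    lines = []
    if structure.title:
        lines.append(f"REMARK {structure.title}")
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(
            f"ATOM {a.index + 1:6d} {a.name:<4s} {a.residue_label:<4s} {1:4d} "
            f"{x:10.3f} {y:10.3f} {z:10.3f} {a.charge:10.4f} {a.radius:8.3f}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Frame ensembles
# ---------------------------------------------------------------------------


def read_frames(path, fmt: str | None = None) -> FrameSet:
    """Read a multi-frame coordinate file (multi-model PDB or XYZ) into a FrameSet.

    Parameters
    ----------
    path : path-like
        Coordinate file.  Coordinates are interpreted as Å.
    fmt : {"pdb", "xyz", None}
        Format override; inferred from the file suffix when None.

    Raises
    ------
    ValueError
        If the frames do not all share one atom count, or the file has no frames.
    """
    import MDAnalysis as mda

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("pdb", "xyz"):
        raise ValueError(f"unsupported frame format {fmt!r}; use 'pdb' or 'xyz'")

    if fmt == "xyz":
        _validate_xyz_atom_counts(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
            frames = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
        except Exception as exc:  # MDAnalysis raises a mix of types for bad input
            raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not frames:
        raise ValueError(f"no frames found in {path}")
    n_atoms = frames[0].shape[0]
    return FrameSet(n_atoms=n_atoms, frames=frames)


def _validate_xyz_atom_counts(path: Path) -> None:
    # MDAnalysis silently truncates on a short trailing XYZ block; enforce the
    # equal-atom-count contract up front with a cheap structural scan.
    lines = path.read_text().splitlines()
    pos = 0
    counts = []
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise ValueError(f"{path}: expected an atom count at line {pos + 1}")
        body = [
            ln
            for ln in lines[pos + 2 : pos + 2 + n]
            if ln.strip()
        ]
        if len(body) != n:
            raise ValueError(
                f"{path}: frame starting at line {pos + 1} declares {n} atoms "
                f"but provides {len(body)}"
            )
        counts.append(n)
        pos += 2 + n
    if len(set(counts)) > 1:
        raise ValueError(f"{path}: inconsistent atom counts across frames: {sorted(set(counts))}")


def write_xyz_frames(frames: FrameSet, path, names: Sequence[str] | None = None) -> None:
    """Write a FrameSet as a multi-frame XYZ file."""
    path = Path(path)
    if names is None:
        names = ["X"] * frames.n_atoms
    blocks = []
    for k, fr in enumerate(frames.frames):
        lines = [str(frames.n_atoms), f"frame {k}"]
        for name, (x, y, z) in zip(names, fr):
            lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
        blocks.append("\n".join(lines))
    path.write_text("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# Protonation states and geometric observables
# ---------------------------------------------------------------------------

ProtonationState = Literal["protonated", "deprotonated"]


def apply_charge_state(
    structure: Structure, site: TitratableSite, state: ProtonationState
) -> Structure:
    """Return a copy of ``structure`` with the site's charges set to ``state``.

    The input structure is taken as the *deprotonated* reference for the
    site's atoms plus the already-applied perturbation if any; concretely
    the operation is idempotent: applying ``"protonated"`` sets charge(i) =
    base(i) + delta_q(i), applying ``"deprotonated"`` sets charge(i) =
    base(i), where base is recovered from the structure's current state.

    To keep idempotency without hidden bookkeeping, the structure is treated
    as currently deprotonated when ``state="protonated"`` is first applied;
    a protonated→deprotonated→protonated cycle therefore recovers the
    original charges exactly.
    """
    if state not in ("protonated", "deprotonated"):
        raise ValueError(f"state must be 'protonated' or 'deprotonated', got {state!r}")
    n = len(structure)
    for idx in site.atom_indices:
        if not (0 <= idx < n):
            raise IndexError(f"site atom index {idx} out of range for {n}-atom structure")
    # Stateless convention: the site records which state the structure is in
    # via a tag on the Structure title?  No — keep it purely functional: the
    # caller owns the bookkeeping.  We store per-site state on the returned
    # structure in `_site_states` so repeated application is idempotent.
    current = getattr(structure, "_site_states", {})
    new_states = dict(current)
    prev = current.get(site.label, "deprotonated")
    atoms = list(structure.atoms)
    for idx, dq in zip(site.atom_indices, site.delta_q):
        q = atoms[idx].charge
        if prev == "protonated":
            q -= dq  # back to deprotonated base
        if state == "protonated":
            q += dq
        atoms[idx] = atoms[idx].with_charge(q)
    new_states[site.label] = state
    out = Structure(atoms=atoms, title=structure.title)
    out._site_states = new_states
    return out


def distance_series(frames: FrameSet, i: int, j: int) -> np.ndarray:
    """Per-frame Euclidean distance between atoms ``i`` and ``j``, Å."""
    if i == j:
        raise ValueError("distance_series requires two distinct atoms")
    for idx in (i, j):
        if not (0 <= idx < frames.n_atoms):
            raise IndexError(f"atom index {idx} out of range for {frames.n_atoms} atoms")
    coords = np.asarray(frames.frames)
    return np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1)
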