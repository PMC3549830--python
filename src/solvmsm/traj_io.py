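"""Trajectory I/O and the Configuration data model.

A *configuration* is one simulation frame reduced to two point sets: the
solute atoms ``X`` (an ``m x 3`` array) and the solvent molecules ``Y``
(an ``n x 3`` array, one point per water — its oxygen).  Every downstream
stage (signatures, metrics, clustering, MSM estimation) consumes these
objects, so the invariants live here: all frames of a trajectory share the
same ``m`` and ``n``, coordinates are finite, and nothing anywhere may
depend on the *order* of the solvent rows.

Supported on-disk formats are multi-frame XYZ (count line, comment line,
``element x y z`` records, frames concatenated) and multi-model PDB
(``MODEL``/``ENDMDL``), the latter via biotite.  Coordinates are taken
verbatim from the file; units are whatever the file uses (Å for PDB by
convention) and σ or cylinder dimensions elsewhere in the package are
interpreted in those same units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Configuration",
    "Trajectory",
    "SelectionSpec",
    "SelectionError",
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "minimum_image_displacement",
]

#: residue names recognised as water in PDB files
WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP3"})
#: atom names recognised as the water oxygen
WATER_OXYGENS = frozenset({"O", "OW"})


class SelectionError(ValueError):
    """A selection rule failed to pick the expected atoms in some frame."""


class TrajectoryFormatError(ValueError):
    """The file violates the expected multi-frame layout."""


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the central orthorhombic image.

    ``delta`` has shape ``(..., 3)``; ``box`` is three edge lengths or None
    (no periodicity).  Explicit-solvent MD is periodic, so signatures of
    molecules near a box edge would be corrupted without this.
    """
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


@dataclass(frozen=True)
class Configuration:
    """One frame: solute point set X (m x 3) and solvent point set Y (n x 3).

    Two configurations that differ only by a permutation of the solvent rows
    are physically identical; every solvent-based quantity in this package
    is invariant under that permutation.
    """

    solute_coords: np.ndarray
    solvent_coords: np.ndarray
    frame_index: int = 0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.solute_coords, dtype=float)
        Y = np.asarray(self.solvent_coords, dtype=float).reshape(-1, 3)
        if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 1:
            raise ValueError(f"solute_coords must be (m>=1, 3), got {X.shape}")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("coordinates must be finite")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        object.__setattr__(self, "solute_coords", X)
        object.__setattr__(self, "solvent_coords", Y)
        if self.box is not None:
            b = np.asarray(self.box, dtype=float)
            if b.shape != (3,) or not (b > 0).all():
                raise ValueError("box must be three positive edge lengths")
            object.__setattr__(self, "box", b)

    @property
    def n_solute(self) -> int:
        return self.solute_coords.shape[0]

    @property
    def n_solvent(self) -> int:
        return self.solvent_coords.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of configurations at a fixed frame interval.

    ``lag_time`` is the physical time between consecutive frames (the MSM
    elementary lag τ); transition counting works in integer frame lags and
    carries τ as metadata.
    """

    frames: list[Configuration]
    lag_time: float = 1.0
    trajectory_id: str = "traj"

    def __post_init__(self) -> None:
        if self.lag_time <= 0:
            raise ValueError("lag_time must be positive")
        if self.frames:
            m = self.frames[0].n_solute
            n = self.frames[0].n_solvent
            for f in self.frames:
                if f.n_solute != m or f.n_solvent != n:
                    raise ValueError(
                        "all frames must share the same solute/solvent counts"
                    )
            idx = [f.frame_index for f in self.frames]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Configuration:
        return self.frames[i]

    @property
    def n_solute(self) -> int:
        return self.frames[0].n_solute

    @property
    def n_solvent(self) -> int:
        return self.frames[0].n_solvent


@dataclass(frozen=True)
class SelectionSpec:
    """Rules picking solute atoms and solvent oxygens out of a frame.

    Either explicit 0-based index lists, or (for PDB) name-based rules:
    solvent oxygens are atoms named O/OW in residues HOH/WAT/SOL/TIP3 and
    the solute is everything in non-water residues.  For XYZ files, which
    carry only element symbols, name-based selection treats ``solute_names``
    / ``solvent_names`` as element symbols.
    """

    solute_indices: tuple[int, ...] | None = None
    solvent_indices: tuple[int, ...] | None = None
    solute_names: frozenset[str] | None = None
    solvent_names: frozenset[str] = WATER_OXYGENS

    def __post_init__(self) -> None:
        if self.solute_indices is not None and self.solvent_indices is not None:
            if set(self.solute_indices) & set(self.solvent_indices):
                raise SelectionError("solute and solvent selections overlap")

    @classmethod
    def from_indices(cls, solute: Iterable[int], solvent: Iterable[int]) -> "SelectionSpec":
        return cls(solute_indices=tuple(solute), solvent_indices=tuple(solvent))


# ---------------------------------------------------------------------------
# XYZ

def _parse_xyz_frames(path: Path):
    """Yield (symbols, coords) per frame of a multi-frame XYZ file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    nlines = len(lines)
    while pos < nlines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        if pos + 2 + natoms > nlines:
            raise TrajectoryFormatError(f"{path}: truncated frame at line {pos + 1}")
        symbols: list[str] = []
        coords = np.empty((natoms, 3), dtype=float)
        for i in range(natoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path}: malformed atom record at line {pos + 3 + i}"
                )
            symbols.append(parts[0])
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        yield symbols, coords
        pos += 2 + natoms


def _select_from_names(
    names: Sequence[str], selection: SelectionSpec, frame_no: int
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a SelectionSpec against per-atom names; returns index arrays."""
    n_atoms = len(names)
    if selection.solvent_indices is not None:
        solv = np.asarray(selection.solvent_indices, dtype=int)
    else:
        solv = np.array(
            [i for i, nm in enumerate(names) if nm.upper() in selection.solvent_names],
            dtype=int,
        )
    if selection.solute_indices is not None:
        solu = np.asarray(selection.solute_indices, dtype=int)
    elif selection.solute_names is not None:
        solu = np.array(
            [i for i, nm in enumerate(names) if nm.upper() in selection.solute_names],
            dtype=int,
        )
    else:
        solv_set = set(solv.tolist())
        solu = np.array([i for i in range(n_atoms) if i not in solv_set], dtype=int)
    for which, idx in (("solute", solu), ("solvent", solv)):
        if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
            raise SelectionError(
                f"frame {frame_no}: {which} selection index out of range "
                f"(file has {n_atoms} atoms)"
            )
    if solu.size < 1:
        raise SelectionError(f"frame {frame_no}: empty solute selection")
    if set(solu.tolist()) & set(solv.tolist()):
        raise SelectionError(f"frame {frame_no}: solute/solvent selections overlap")
    return solu, solv


# ---------------------------------------------------------------------------
# PDB (via biotite)

def _read_pdb(path: Path, selection: SelectionSpec, lag_time: float, traj_id: str) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)  # AtomArrayStack, coords in Å
    atom_names = [nm.upper() for nm in stack.atom_name]
    res_names = [nm.upper() for nm in stack.res_name]
    n_atoms = len(atom_names)

    if selection.solvent_indices is not None:
        solv = np.asarray(selection.solvent_indices, dtype=int)
    else:
        solv = np.array(
            [
                i
                for i in range(n_atoms)
                if res_names[i] in WATER_RESIDUES
                and atom_names[i] in selection.solvent_names
            ],
            dtype=int,
        )
    if selection.solute_indices is not None:
        solu = np.asarray(selection.solute_indices, dtype=int)
    elif selection.solute_names is not None:
        solu = np.array(
            [i for i in range(n_atoms) if atom_names[i] in selection.solute_names],
            dtype=int,
        )
    else:
        solu = np.array(
            [i for i in range(n_atoms) if res_names[i] not in WATER_RESIDUES],
            dtype=int,
        )
    if solu.size < 1:
        raise SelectionError("empty solute selection")
    if set(solu.tolist()) & set(solv.tolist()):
        raise SelectionError("solute/solvent selections overlap")

    frames = []
    coords = stack.coord  # (n_models, n_atoms, 3)
    for k in range(coords.shape[0]):
        frames.append(
            Configuration(
                solute_coords=np.array(coords[k, solu], dtype=float),
                solvent_coords=np.array(coords[k, solv], dtype=float),
                frame_index=k,
            )
        )
    if not frames:
        raise TrajectoryFormatError(f"{path}: no models found")
    return Trajectory(frames=frames, lag_time=lag_time, trajectory_id=traj_id)


# ---------------------------------------------------------------------------
# public API

def read_trajectory(
    path: str | Path,
    format: str = "xyz",
    selection: SelectionSpec | None = None,
    lag_time: float = 1.0,
) -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB file into a Trajectory.

    Parameters
    ----------
    path : path to the file.
    format : ``"xyz"`` or ``"pdb"``.
    selection : which atoms are solute and which are solvent oxygens.
        Defaults to name-based water detection (PDB) or element ``O``/``OW``
        as solvent (XYZ).
    lag_time : physical time between consecutive frames (τ).

    Frames are returned in file order with coordinates exactly as parsed.
    A frame in which a selected atom is missing raises :class:`SelectionError`
    naming the frame; inconsistent atom counts raise
    :class:`TrajectoryFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if selection is None:
        selection = SelectionSpec()
    traj_id = path.stem
    if format == "pdb":
        return _read_pdb(path, selection, lag_time, traj_id)
    if format != "xyz":
        raise ValueError(f"unknown format {format!r}")

    frames = []
    ref_counts: tuple[int, int] | None = None
    n_atoms_ref: int | None = None
    for k, (symbols, coords) in enumerate(_parse_xyz_frames(path)):
        if n_atoms_ref is None:
            n_atoms_ref = len(symbols)
        elif len(symbols) != n_atoms_ref:
            raise TrajectoryFormatError(
                f"{path}: frame {k} has {len(symbols)} atoms, expected {n_atoms_ref}"
            )
        solu, solv = _select_from_names(symbols, selection, k)
        if ref_counts is None:
            ref_counts = (solu.size, solv.size)
        elif (solu.size, solv.size) != ref_counts:
            raise SelectionError(
                f"frame {k}: selection picked {(solu.size, solv.size)} atoms, "
                f"expected {ref_counts}"
            )
        frames.append(
            Configuration(
                solute_coords=coords[solu],
                solvent_coords=coords[solv],
                frame_index=k,
            )
        )
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return Trajectory(frames=frames, lag_time=lag_time, trajectory_id=traj_id)


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    format: str = "xyz",
    solute_element: str = "C",
    solvent_element: str = "O",
) -> None:
    """Write a trajectory as multi-frame XYZ or multi-model PDB.

    Solute atoms are written first, then solvent, with fixed element/atom
    names so that :func:`read_trajectory` with the matching selection (or
    defaults, for PDB) round-trips the coordinates at the format's printed
    precision.
    """
    if not traj.frames:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    if format == "xyz":
        with open(path, "w") as fh:
            for conf in traj.frames:
                n_total = conf.n_solute + conf.n_solvent
                fh.write(f"{n_total}\n")
                fh.write(f"frame {conf.frame_index} {traj.trajectory_id}\n")
                for x, y, z in conf.solute_coords:
                    fh.write(f"{solute_element} {x:.8f} {y:.8f} {z:.8f}\n")
                for x, y, z in conf.solvent_coords:
                    fh.write(f"{solvent_element} {x:.8f} {y:.8f} {z:.8f}\n")
        return
    if format != "pdb":
        raise ValueError(f"unknown format {format!r}")

    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    m, n = traj.n_solute, traj.n_solvent
    n_atoms = m + n
    template = struc.AtomArray(n_atoms)
    template.coord = np.zeros((n_atoms, 3), dtype=np.float32)
    template.chain_id = np.array(["A"] * m + ["W"] * n)
    template.res_id = np.concatenate([np.ones(m, dtype=int), 2 + np.arange(n)])
    template.res_name = np.array(["LIG"] * m + ["HOH"] * n)
    template.atom_name = np.array(
        [f"{solute_element}{i + 1}" for i in range(m)] + ["O"] * n
    )
    template.element = np.array([solute_element] * m + ["O"] * n)
    template.hetero = np.array([False] * m + [True] * n)

    coords = np.stack(
        [
            np.vstack([c.solute_coords, c.solvent_coords]).astype(np.float32)
            for c in traj.frames
        ]
    )
    stack = struc.AtomArrayStack(len(traj.frames), n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
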