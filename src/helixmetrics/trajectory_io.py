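"""Topology/trajectory reading, atom selection and frame windowing.

File formats (PDB topology, DCD or multi-model PDB coordinates) are handled
by MDAnalysis; this module exposes lightweight in-memory containers so the
analysis code never touches a Universe directly.

Conventions used throughout the package:

* lengths in angstroms, times in picoseconds, angles in degrees;
* residue numbers are taken verbatim from the input file (an integer offset
  between numbering schemes, where needed, is applied by the caller);
* frame windows are half-open ``(start, end]`` anchored at the window end,
  so "last 100 ns sampled every 10 ps" yields exactly 10,000 frames.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SelectionSpec",
    "TrajectoryError",
    "DEFAULT_WATER_ATOM_NAMES",
    "DEFAULT_WATER_RESIDUE_NAMES",
    "read_topology",
    "read_trajectory",
    "write_topology",
    "write_trajectory",
    "select_atoms",
    "select_water_oxygens",
    "select_frames",
]

# Water-naming dialects vary across PDB writers; both sets are configurable
# at the call sites that use them.
DEFAULT_WATER_ATOM_NAMES = frozenset({"OH2", "OW", "O"})
DEFAULT_WATER_RESIDUE_NAMES = frozenset({"TIP3", "HOH", "WAT", "SOL"})


class TrajectoryError(ValueError):
    """Raised for malformed topology/trajectory input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, as read from the file."""

    atom_index: int  # 0-based position in the topology
    atom_name: str
    residue_number: int  # verbatim file numbering
    residue_name: str
    segment_id: str = ""
    element: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise TrajectoryError(f"atom {self.atom_index}: empty atom name")


@dataclass
class Frame:
    """Coordinates of every atom at one stored time point."""

    coordinates: np.ndarray  # (n_atoms, 3), angstrom
    time: float  # ps
    box: np.ndarray | None = None  # orthorhombic edge lengths (3,), angstrom

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("frame coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise TrajectoryError(f"non-positive box edge in {self.box}")
        if self.time < 0:
            raise TrajectoryError(f"negative frame time {self.time}")


@dataclass
class Trajectory:
    """An ordered list of frames bound to a topology."""

    topology: list[AtomRecord]
    frames: list[Frame]
    nominal_dt: float  # ps between stored frames

    def __post_init__(self) -> None:
        if self.nominal_dt <= 0:
            raise TrajectoryError(f"nominal_dt must be > 0, got {self.nominal_dt}")
        n_atoms = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n_atoms:
                raise TrajectoryError(
                    f"frame {i}: {fr.coordinates.shape[0]} atoms, topology has {n_atoms}"
                )
        times = [fr.time for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunctive atom selection: every given field must match.

    All fields are optional; an all-``None`` spec selects every atom.
    ``residue_range`` is an inclusive ``(lo, hi)`` pair in file numbering.
    """

    atom_names: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None
    residue_names: frozenset[str] | None = None
    segment_id: str | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not lo <= atom.residue_number <= hi:
                return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.segment_id is not None and atom.segment_id != self.segment_id:
            return False
        return True


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _records_from_universe(u: "mda.Universe") -> list[AtomRecord]:
    atoms = u.atoms
    try:
        elements = atoms.elements
    except mda.exceptions.NoDataError:
        elements = [""] * len(atoms)
    try:
        segids = atoms.segids
    except mda.exceptions.NoDataError:
        segids = [""] * len(atoms)
    return [
        AtomRecord(
            atom_index=i,
            atom_name=str(name),
            residue_number=int(resid),
            residue_name=str(resname),
            segment_id=str(segid).strip(),
            element=str(elem).strip(),
        )
        for i, (name, resid, resname, segid, elem) in enumerate(
            zip(atoms.names, atoms.resids, atoms.resnames, segids, elements)
        )
    ]


def _validate_pdb_lines(path: str) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise TrajectoryError(f"{path}:{lineno}: truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise TrajectoryError(
                    f"{path}:{lineno}: unparseable ATOM record ({exc})"
                ) from None


def read_topology(path: str | os.PathLike) -> list[AtomRecord]:
    """Read a PDB file into a list of :class:`AtomRecord`.

    Residue numbering is preserved verbatim. Raises :class:`TrajectoryError`
    naming the offending line for unparseable records, and for files that
    contain no atoms.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path)
        except (ValueError, IndexError, EOFError) as exc:
            raise TrajectoryError(f"{path}: cannot parse PDB ({exc})") from exc
    if len(u.atoms) == 0:
        raise TrajectoryError(f"{path}: no atoms")
    return _records_from_universe(u)


def read_trajectory(
    topology: list[AtomRecord],
    path: str | os.PathLike,
    *,
    topology_path: str | os.PathLike | None = None,
    nominal_dt: float | None = None,
) -> Trajectory:
    """Read a DCD (or multi-model PDB) coordinate file against *topology*.

    Frame times come from the DCD header when present, otherwise
    ``frame_index * nominal_dt`` (default 1 ps). The coordinate file's atom
    count must match the topology.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology_path is not None:
            u = mda.Universe(os.fspath(topology_path), path)
        else:
            # an in-memory minimal topology carrying only the atom count
            u = mda.Universe.empty(len(topology), trajectory=False)
            try:
                u.load_new(path)
            except (ValueError, IOError) as exc:
                raise TrajectoryError(
                    f"{path}: atom count does not match topology "
                    f"({len(topology)} atoms expected): {exc}"
                ) from exc
        if u.trajectory.n_atoms != len(topology):
            raise TrajectoryError(
                f"{path}: file has {u.trajectory.n_atoms} atoms, "
                f"topology has {len(topology)}"
            )
        frames: list[Frame] = []
        header_dt = None
        try:
            header_dt = float(u.trajectory.dt)
        except (AttributeError, ValueError):
            pass
        dt = nominal_dt if nominal_dt is not None else (header_dt or 1.0)
        dt = _snap(dt)
        for i, ts in enumerate(u.trajectory):
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.array(ts.dimensions[:3], dtype=float)
            # stored frames are uniformly spaced; regenerate times from the
            # (snapped) header dt so window/stride arithmetic stays exact
            frames.append(Frame(np.array(ts.positions, dtype=float), time=i * dt, box=box))
    return Trajectory(topology=topology, frames=frames, nominal_dt=dt)


def _snap(dt: float, rel_tol: float = 1e-5) -> float:
    """Round *dt* to a clean decimal when within unit-conversion error.

    DCD headers store the time step in internal (AKMA) units; converting
    back to ps introduces relative errors of ~1e-8 that would otherwise
    defeat exact stride arithmetic.
    """
    for decimals in (0, 1, 2, 3):
        snapped = round(dt, decimals)
        if snapped > 0 and abs(snapped - dt) <= rel_tol * max(1.0, abs(dt)):
            return snapped
    return dt


# ---------------------------------------------------------------------------
# writing (used by the synthetic generator)
# ---------------------------------------------------------------------------


def write_topology(path: str | os.PathLike, topology: list[AtomRecord], coordinates: np.ndarray, box: np.ndarray | None = None) -> None:
    """Write a single-frame PDB for *topology* at *coordinates*."""
    path = os.fspath(path)
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (len(topology), 3):
        raise TrajectoryError(
            f"coordinates shape {coordinates.shape} does not match topology "
            f"({len(topology)} atoms)"
        )
    lines = []
    if box is not None:
        bx, by, bz = np.asarray(box, dtype=float)
        lines.append(
            f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for atom, (x, y, z) in zip(topology, coordinates):
        serial = (atom.atom_index + 1) % 100000
        name = atom.atom_name
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        lines.append(
            f"ATOM  {serial:5d} {name_field}{'':1s}{atom.residue_name[:4]:<4s}"
            f"{'A':1s}{atom.residue_number % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
            f"{atom.segment_id[:4]:<4s}{atom.element[:2]:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trajectory(path: str | os.PathLike, trajectory: Trajectory) -> None:
    """Write frames to a CHARMM/NAMD-flavour DCD file (single precision)."""
    path = os.fspath(path)
    n_atoms = trajectory.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.coordinates.DCD.DCDWriter(path, n_atoms, dt=trajectory.nominal_dt) as w:
            u = mda.Universe.empty(n_atoms, trajectory=True)
            for fr in trajectory.frames:
                u.atoms.positions = fr.coordinates
                if fr.box is not None:
                    u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_atoms(topology: Sequence[AtomRecord], spec: SelectionSpec) -> list[int]:
    """Return ascending atom indices matching *spec* (empty list allowed)."""
    return [a.atom_index for a in topology if spec.matches(a)]


def select_water_oxygens(
    topology: Sequence[AtomRecord],
    atom_names: Iterable[str] = DEFAULT_WATER_ATOM_NAMES,
    residue_names: Iterable[str] = DEFAULT_WATER_RESIDUE_NAMES,
) -> list[int]:
    """Water oxygen indices under the configurable naming dialects."""
    spec = SelectionSpec(
        atom_names=frozenset(atom_names), residue_names=frozenset(residue_names)
    )
    return select_atoms(topology, spec)


def select_frames(
    trajectory: Trajectory,
    window_start: float,
    window_end: float,
    stride: float,
) -> Trajectory:
    """Slice frames in the half-open window ``(window_start, window_end]``.

    Kept frames satisfy ``start < t <= end`` with ``(end - t)`` an integer
    multiple of *stride*, so a fully covered window yields exactly
    ``(end - start) / stride`` frames. *stride* must be a positive integer
    multiple of the stored ``nominal_dt``.
    """
    if window_start >= window_end:
        raise TrajectoryError(
            f"window_start ({window_start}) must be < window_end ({window_end})"
        )
    if stride <= 0:
        raise TrajectoryError(f"stride must be > 0, got {stride}")
    dt = trajectory.nominal_dt
    ratio = stride / dt
    if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
        raise TrajectoryError(
            f"stride {stride} ps is not an integer multiple of the stored dt {dt} ps"
        )
    times = trajectory.times
    if len(times) == 0:
        raise TrajectoryError("empty trajectory")
    tol = 1e-6 * max(1.0, stride)
    if window_end > times[-1] + tol or window_start < times[0] - dt - tol:
        raise TrajectoryError(
            f"window ({window_start}, {window_end}] outside trajectory time range "
            f"[{times[0]}, {times[-1]}]"
        )
    kept = []
    for fr in trajectory.frames:
        t = fr.time
        if not (window_start + tol < t <= window_end + tol):
            continue
        k = (window_end - t) / stride
        if abs(k - round(k)) <= 1e-6:
            kept.append(fr)
    return Trajectory(topology=trajectory.topology, frames=kept, nominal_dt=stride)


def last_n_window(trajectory: Trajectory, n_ps: float) -> tuple[float, float]:
    """Window bounds for "the last *n_ps* ps", anchored at the final frame."""
    end = float(trajectory.times[-1])
    return end - n_ps, end
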