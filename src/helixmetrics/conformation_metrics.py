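"""Intracellular-domain metrics: membrane contact and Box1 solvent exposure.

Cytokine receptors carry a membrane-proximal Box1 motif on the
intracellular (IC) domain that must be accessible to bind a Janus kinase.
Two simple per-frame metrics quantify how an IC region sits relative to
the bilayer:

* the minimum distance of the region's atoms to the nearer phosphorus
  leaflet plane (small = membrane-contacting);
* a solvent-exposure proxy: the number of water oxygens within a cutoff
  (default 4 A, roughly a first hydration shell) of any region atom. An
  "open" loop is water-exposed; a loop packed against the membrane or
  against other residues is not.

Region residue numbers are interpreted in a configurable numbering scheme
(an integer offset against file numbering), because IC-local and
full-length numbering schemes both occur in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .membrane_geometry import MembraneGeometry, signed_depth
from .trajectory_io import AtomRecord, Frame, SelectionSpec, Trajectory, select_atoms

__all__ = [
    "RegionDefinition",
    "RegionMetricSeries",
    "resolve_region_atoms",
    "region_membrane_distance",
    "box1_exposure",
    "region_metric_series",
]

DEFAULT_EXPOSURE_CUTOFF = 4.0  # angstrom


@dataclass(frozen=True)
class RegionDefinition:
    """A labelled residue range of the intracellular domain."""

    label: str
    residue_range: tuple[int, int]  # inclusive, in the configured scheme
    atom_scope: str = "heavy-atoms"  # or "CA-only"
    numbering_offset: int = 0  # file resid = configured resid + offset

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError(f"region {self.label!r}: empty residue range {self.residue_range}")
        if self.atom_scope not in ("heavy-atoms", "CA-only"):
            raise ValueError(f"region {self.label!r}: unknown atom scope {self.atom_scope!r}")


@dataclass(frozen=True)
class RegionMetricSeries:
    """Per-frame membrane distance and hydration count for one region."""

    label: str
    times: np.ndarray  # ps
    min_membrane_distance: np.ndarray  # angstrom
    hydration_count: np.ndarray  # integer waters per frame


def resolve_region_atoms(topology: list[AtomRecord], region: RegionDefinition) -> list[int]:
    """Atom indices of *region* in file numbering; error if none resolve."""
    lo, hi = region.residue_range
    lo += region.numbering_offset
    hi += region.numbering_offset
    names = frozenset({"CA"}) if region.atom_scope == "CA-only" else None
    idx = select_atoms(topology, SelectionSpec(atom_names=names, residue_range=(lo, hi)))
    if names is None:
        # heavy atoms: drop hydrogens and waters by element/name heuristics
        idx = [
            i for i in idx
            if not topology[i].atom_name.startswith(("H", "1H", "2H", "3H"))
            and topology[i].residue_name not in ("TIP3", "HOH", "WAT", "SOL")
        ]
    if not idx:
        raise ValueError(
            f"region {region.label!r} (residues {lo}-{hi} after offset "
            f"{region.numbering_offset}) resolves to no atoms: check the numbering scheme"
        )
    return idx


def region_membrane_distance(
    frame: Frame, region_atom_indices: list[int], geometry: MembraneGeometry
) -> float:
    """Minimum distance of the region's atoms to the closer leaflet plane.

    Each atom's signed depth is compared against both leaflet offsets; the
    returned value is the smallest ``|depth - offset|`` over atoms and
    leaflets. Membrane-contacting regions give values near 0.
    """
    if not region_atom_indices:
        raise ValueError("region resolves to no atoms")
    pts = frame.coordinates[np.asarray(region_atom_indices, int)]
    depths = (pts - geometry.midplane_point) @ geometry.normal
    dists = np.abs(depths[:, None] - np.asarray(geometry.leaflet_offsets)[None, :])
    return float(dists.min())


def box1_exposure(
    frame: Frame,
    region_atom_indices: list[int],
    water_indices: list[int],
    cutoff: float = DEFAULT_EXPOSURE_CUTOFF,
) -> int:
    """Number of water oxygens within *cutoff* of any region atom.

    Minimum-image distances when the frame has a box. Higher counts mean a
    more open, solvent-exposed loop.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if not water_indices:
        raise ValueError("empty water selection")
    if not region_atom_indices:
        raise ValueError("region resolves to no atoms")
    waters = frame.coordinates[np.asarray(water_indices, int)]
    within = np.zeros(len(water_indices), dtype=bool)
    for i in region_atom_indices:
        d = waters - frame.coordinates[i]
        if frame.box is not None:
            d -= frame.box * np.round(d / frame.box)
        within |= (d**2).sum(axis=1) <= cutoff**2
    return int(within.sum())


def region_metric_series(
    trajectory: Trajectory,
    region: RegionDefinition,
    geometries: list[MembraneGeometry],
    water_indices: list[int],
    cutoff: float = DEFAULT_EXPOSURE_CUTOFF,
) -> RegionMetricSeries:
    """Evaluate both region metrics on every frame of a windowed trajectory."""
    if len(geometries) != trajectory.n_frames:
        raise ValueError("one MembraneGeometry per frame required")
    atom_idx = resolve_region_atoms(trajectory.topology, region)
    dists = []
    counts = []
    for fr, geom in zip(trajectory.frames, geometries):
        dists.append(region_membrane_distance(fr, atom_idx, geom))
        counts.append(box1_exposure(fr, atom_idx, water_indices, cutoff))
    return RegionMetricSeries(
        label=region.label,
        times=trajectory.times,
        min_membrane_distance=np.array(dists),
        hydration_count=np.array(counts, dtype=int),
    )
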