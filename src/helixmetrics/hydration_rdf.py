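"""Water-residue radial distribution functions under periodic boundaries.

The water RDF around a residue's Cbeta atom measures how deeply that
residue is buried from solvent: a buried residue has an empty first
hydration shell, an interfacial one does not. Distances use the
minimum-image convention for orthorhombic boxes.

Normalisation. ``g(r)`` divides the mean per-frame pair count in each
shell by ``rho_ref * V_shell``. Two reference densities are offered:

``box-density``
    ``rho_ref = n_waters / V_box``. In a membrane system water is excluded
    from the slab, so g(r) plateaus below 1; curves are still directly
    comparable across variants under the same box. This is the default.
``plateau``
    g is rescaled after binning so the mean over the outer 20% of bins is
    1, for readers who expect a bulk-normalised curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory

__all__ = ["RDFResult", "minimum_image_distance", "water_rdf", "coordination_number"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RDFResult:
    """Binned g(r) between one center atom and a set of water oxygens."""

    bin_edges: np.ndarray  # (n_bins+1,), uniform from 0 to r_max, angstrom
    g_values: np.ndarray  # (n_bins,), dimensionless
    pair_counts: np.ndarray  # (n_bins,), raw integer counts summed over frames
    reference_density: float  # waters / angstrom^3
    n_frames: int
    center_label: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def minimum_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray | None) -> float:
    """Euclidean distance between *p* and *q* under the minimum-image rule.

    Each Cartesian component of ``p - q`` is wrapped into
    ``[-edge/2, edge/2]`` before taking the norm. With ``box=None`` the
    plain Euclidean distance is returned.
    """
    d = np.asarray(p, float) - np.asarray(q, float)
    if box is not None:
        box = np.asarray(box, float)
        d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def _minimum_image_distances(center: np.ndarray, points: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    d = points - center
    if box is not None:
        d -= box * np.round(d / box)
    return np.sqrt((d**2).sum(axis=1))


def water_rdf(
    trajectory: Trajectory,
    center_index: int,
    water_indices: list[int],
    r_max: float = 15.0,
    bin_width: float = 0.1,
    normalization: str = "box-density",
    center_label: str = "",
) -> RDFResult:
    """g(r) between one center atom (a Cbeta) and the water oxygens.

    The trajectory is expected to be windowed/strided already. *r_max*
    must not exceed half the smallest box edge (minimum-image validity).
    Frames without box information fall back to non-periodic distances,
    with a loud log message.
    """
    if not water_indices:
        raise ValueError("empty water selection")
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    if normalization not in ("box-density", "plateau"):
        raise ValueError(f"unknown normalization {normalization!r}")
    n_bins = int(round(r_max / bin_width))
    if abs(n_bins * bin_width - r_max) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide r_max {r_max}")
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    widx = np.asarray(water_indices, int)
    inv_volume_sum = 0.0
    n_noperiodic = 0
    for fr in trajectory.frames:
        if fr.box is not None:
            if r_max > fr.box.min() / 2 + 1e-9:
                raise ValueError(
                    f"r_max {r_max} A exceeds half the smallest box edge "
                    f"({fr.box.min() / 2:.2f} A): minimum image invalid"
                )
            inv_volume_sum += 1.0 / float(np.prod(fr.box))
        else:
            n_noperiodic += 1
        d = _minimum_image_distances(fr.coordinates[center_index], fr.coordinates[widx], fr.box)
        c, _ = np.histogram(d, bins=edges)
        counts += c
    if n_noperiodic:
        logger.warning(
            "%d/%d frames had no box information; non-periodic distances used",
            n_noperiodic, trajectory.n_frames,
        )
    n_frames = trajectory.n_frames
    if inv_volume_sum > 0:
        mean_inv_volume = inv_volume_sum / (n_frames - n_noperiodic)
        reference_density = len(widx) * mean_inv_volume
    else:
        # no periodic information at all: normalise against a unit density
        reference_density = float("nan")
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    mean_counts = counts / n_frames
    if np.isnan(reference_density):
        g = mean_counts / shell_volumes
    else:
        g = mean_counts / (reference_density * shell_volumes)
    if normalization == "plateau":
        tail = g[int(np.ceil(0.8 * n_bins)):]
        tail_mean = tail.mean()
        if tail_mean <= 0:
            raise ValueError("plateau normalization impossible: outer bins are empty")
        g = g / tail_mean
        reference_density = reference_density * tail_mean
    return RDFResult(
        bin_edges=edges,
        g_values=g,
        pair_counts=counts,
        reference_density=float(reference_density),
        n_frames=n_frames,
        center_label=center_label,
    )


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """Mean number of waters within *r_cut* of the center, per frame.

    Computed from the raw pair counts (not from g), so it is exact for the
    binning used; monotone non-decreasing in *r_cut*. *r_cut* is rounded
    down to the nearest bin edge.
    """
    r_max = float(rdf.bin_edges[-1])
    if r_cut > r_max + 1e-9:
        raise ValueError(f"r_cut {r_cut} exceeds r_max {r_max}")
    if r_cut < 0:
        raise ValueError("r_cut must be >= 0")
    n_full = int(np.searchsorted(rdf.bin_edges, r_cut + 1e-12) ) - 1
    n_full = max(n_full, 0)
    return float(rdf.pair_counts[:n_full].sum() / rdf.n_frames)
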