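"""Bilayer frame estimation from lipid phosphorus atoms.

The bilayer is represented per frame by its midplane point, a unit normal
oriented toward the extracellular side, and the two signed leaflet offsets
(distances of the phosphorus headgroup planes from the midplane along the
normal). No time averaging is done: membranes deform, so each frame gets
its own geometry.

Two estimation modes are provided:

``fixed-z``
    The normal is the lab z-axis and the midplane z is the mean phosphorus
    z. Appropriate when the system was built with the bilayer normal along
    a box axis (the default here).
``fitted``
    The normal is the smallest-principal-component eigenvector of the
    phosphorus coordinates (the direction of least spread of a planar
    slab), the midplane is the phosphorus centroid. Use for tilted or
    drifted membranes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory_io import Frame

__all__ = ["MembraneGeometry", "MembraneGeometryError", "estimate_membrane_geometry", "signed_depth"]

logger = logging.getLogger(__name__)

#: |leaflet offset| range considered physical for a lipid bilayer (angstrom)
PHYSICAL_OFFSET_RANGE = (10.0, 30.0)


class MembraneGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class MembraneGeometry:
    """Per-frame bilayer frame: midplane, oriented normal, leaflet planes."""

    midplane_point: np.ndarray  # (3,), angstrom
    normal: np.ndarray  # unit (3,), toward the extracellular side
    leaflet_offsets: tuple[float, float]  # signed, (extracellular, intracellular)
    frame_time: float  # ps

    def __post_init__(self) -> None:
        object.__setattr__(self, "midplane_point", np.asarray(self.midplane_point, float))
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise MembraneGeometryError(f"normal not unit length: |n|={np.linalg.norm(n)}")
        object.__setattr__(self, "normal", n)
        a, b = self.leaflet_offsets
        if a * b >= 0:
            raise MembraneGeometryError(
                f"leaflet offsets must have opposite signs, got {self.leaflet_offsets}"
            )


def estimate_membrane_geometry(
    frame: Frame,
    phosphorus_indices: list[int],
    mode: str = "fixed-z",
    extracellular_reference: np.ndarray | None = None,
) -> MembraneGeometry:
    """Estimate the bilayer frame from phosphorus positions in *frame*.

    Parameters
    ----------
    phosphorus_indices
        Atom indices of the headgroup phosphorus atoms; at least 6, with
        both leaflets represented.
    mode
        ``"fixed-z"`` (default) or ``"fitted"``; see module docstring.
    extracellular_reference
        A point known to lie on the extracellular side (e.g. the Calpha of
        the first, lowest-numbered TM residue). The normal's sign is chosen
        so this point has positive signed depth. Defaults to +z orientation.
    """
    if len(phosphorus_indices) < 6:
        raise MembraneGeometryError(
            f"need >= 6 phosphorus atoms, got {len(phosphorus_indices)}"
        )
    pts = frame.coordinates[np.asarray(phosphorus_indices, int)]
    centroid = pts.mean(axis=0)
    if mode == "fixed-z":
        normal = np.array([0.0, 0.0, 1.0])
        midplane = np.array([0.0, 0.0, centroid[2]])
    elif mode == "fitted":
        centered = pts - centroid
        # initial guess: direction of least spread of the whole cloud
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1] / np.linalg.norm(vt[-1])
        # refine by removing the leaflet separation: the pooled cloud has
        # large variance along the normal (two planes ~40 A apart), which
        # contaminates the smallest principal component for patches whose
        # lateral extent is comparable to the bilayer thickness. Centering
        # each leaflet before the SVD leaves two thin coplanar sheets.
        for _ in range(2):
            proj = centered @ normal
            up = centered[proj > 0]
            dn = centered[proj < 0]
            if len(up) == 0 or len(dn) == 0:
                break
            pooled = np.vstack([up - up.mean(axis=0), dn - dn.mean(axis=0)])
            _, _, vt = np.linalg.svd(pooled, full_matrices=False)
            new = vt[-1] / np.linalg.norm(vt[-1])
            if np.dot(new, normal) < 0:
                new = -new
            normal = new
        midplane = centroid
    else:
        raise MembraneGeometryError(f"unknown mode {mode!r}")

    if extracellular_reference is not None:
        if np.dot(np.asarray(extracellular_reference, float) - midplane, normal) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal

    proj = (pts - midplane) @ normal
    upper = proj[proj > 0]
    lower = proj[proj < 0]
    if len(upper) == 0 or len(lower) == 0:
        raise MembraneGeometryError(
            "cannot split leaflets: all phosphorus atoms on one side of the midplane"
        )
    offsets = (float(upper.mean()), float(lower.mean()))
    lo, hi = PHYSICAL_OFFSET_RANGE
    for off in offsets:
        if not lo <= abs(off) <= hi:
            logger.warning(
                "leaflet offset %.1f A outside the physical range [%g, %g] A at t=%s ps",
                off, lo, hi, frame.time,
            )
    return MembraneGeometry(
        midplane_point=midplane,
        normal=normal,
        leaflet_offsets=offsets,
        frame_time=frame.time,
    )


def signed_depth(position: np.ndarray, geometry: MembraneGeometry) -> float:
    """Signed distance of *position* from the midplane along the normal.

    Positive values are on the extracellular side.
    """
    return float(np.dot(np.asarray(position, float) - geometry.midplane_point, geometry.normal))
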