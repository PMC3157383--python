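"""Helix-axis fitting, tilt and azimuthal (torsion) angles, circular stats.

The two orientation observables of a single-pass transmembrane helix:

tilt angle
    Angle between the fitted helix axis and the membrane normal, folded
    into [0, 90] deg via ``arccos |axis . normal|`` so the estimate is
    insensitive to the sign of the axis. 0 deg means the helix is inserted
    exactly along the normal.
azimuthal angle
    Rotation of the helix about the membrane normal relative to the
    intracellular domain, measured as the IUPAC dihedral over four chosen
    Calpha atoms; range (-180, 180].

Summaries report both linear and circular statistics. Tilt lives on a
bounded range and is summarised linearly; azimuthal angles wrap, so the
circular mean (argument of the mean resultant vector) with the mean
resultant length R is the appropriate summary. When R is small the
circular mean is unreliable; the summary carries an explicit flag for
that (R < 0.2, roughly the value a uniform 360-deg spread produces).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .membrane_geometry import MembraneGeometry, estimate_membrane_geometry
from .trajectory_io import Trajectory

__all__ = [
    "HelixAxis",
    "AngleSeries",
    "AngleSummary",
    "fit_helix_axis",
    "tilt_angle",
    "torsion_angle",
    "angle_series",
    "summarize_angles",
    "angle_histogram",
]

logger = logging.getLogger(__name__)

#: rms deviation of Calpha from the fitted line above which the "helix"
#: is too distorted for the axis to be meaningful (warning only)
RMS_FIT_WARN = 3.0
#: mean resultant length below which the circular mean is flagged unreliable
WEAK_CONCENTRATION_R = 0.2


@dataclass(frozen=True)
class HelixAxis:
    """Least-squares axis of a helical segment for one frame."""

    axis: np.ndarray  # unit (3,), first residue -> last residue
    centroid: np.ndarray  # (3,), angstrom
    residue_range: tuple[int, int]
    rms_fit: float  # angstrom, RMS distance of Calpha from the fitted line


@dataclass(frozen=True)
class AngleSeries:
    """Time series of one angular observable."""

    times: np.ndarray  # ps
    values: np.ndarray  # degrees, inside `wrap`
    kind: str  # "tilt" | "azimuthal"
    wrap: tuple[float, float]  # [0, 90] for tilt, (-180, 180] for azimuthal

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        lo, hi = self.wrap
        if self.values.size and (self.values.min() < lo - 1e-9 or self.values.max() > hi + 1e-9):
            raise ValueError(f"values outside wrap range {self.wrap}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AngleSummary:
    """Linear and circular summaries of an angle series (degrees)."""

    linear_mean: float
    linear_sd: float
    circular_mean: float
    circular_sd: float  # sqrt(-2 ln R), in degrees
    resultant_length: float  # R, in [0, 1]
    n: int
    weakly_concentrated: bool = False  # R < 0.2: circular mean unreliable


def fit_helix_axis(
    frame_coordinates: np.ndarray,
    ca_indices: list[int],
    residue_range: tuple[int, int] = (0, 0),
) -> HelixAxis:
    """Fit the helix axis through the Calpha atoms by SVD.

    The axis is the first right-singular vector of the mean-centred Calpha
    coordinates (direction of greatest spread), with the sign chosen so it
    points from the first toward the last residue in *ca_indices* order.
    ``rms_fit`` is the RMS perpendicular distance of the Calpha atoms from
    the fitted line; values above ~3 A indicate the segment is no longer
    meaningfully helical/straight and trigger a logged warning.
    """
    if len(ca_indices) < 4:
        raise ValueError(f"need >= 4 Calpha atoms, got {len(ca_indices)}")
    pts = np.asarray(frame_coordinates, float)[np.asarray(ca_indices, int)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate Calpha coordinates (all coincident)")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    perp = centered - np.outer(centered @ axis, axis)
    rms_fit = float(np.sqrt((perp**2).sum(axis=1).mean()))
    if rms_fit > RMS_FIT_WARN:
        logger.warning(
            "helix axis fit rms %.2f A exceeds %.1f A: segment may be unwound",
            rms_fit, RMS_FIT_WARN,
        )
    return HelixAxis(axis=axis, centroid=centroid, residue_range=residue_range, rms_fit=rms_fit)


def tilt_angle(axis: HelixAxis | np.ndarray, geometry: MembraneGeometry | np.ndarray) -> float:
    """Tilt of the helix axis against the membrane normal, degrees in [0, 90].

    Uses ``arccos |axis . normal|``: antiparallel axes give the same tilt,
    so sign flips of the axis estimator cannot produce 180-deg jumps.
    """
    a = axis.axis if isinstance(axis, HelixAxis) else np.asarray(axis, float)
    n = geometry.normal if isinstance(geometry, MembraneGeometry) else np.asarray(geometry, float)
    c = abs(float(np.dot(a, n)) / (np.linalg.norm(a) * np.linalg.norm(n)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def torsion_angle(p1, p2, p3, p4) -> float:
    """IUPAC dihedral over four points, degrees in (-180, 180].

    Signed angle between the (p1,p2,p3) and (p2,p3,p4) planes, sign by the
    right-hand rule about the p2->p3 bond: looking from p2 toward p3, a
    positive angle means p4 is rotated clockwise from p1. cis = 0,
    trans = 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    if n1n < 1e-10 or n2n < 1e-10:
        raise ValueError("undefined torsion: three consecutive points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = float(np.degrees(np.arctan2(y, x)))
    # wrap into (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_azimuth(values: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(values, float) + 180.0, 360.0) - 180.0)
    return wrapped


def angle_series(
    trajectory: Trajectory,
    observable: str,
    *,
    ca_indices: list[int] | None = None,
    phosphorus_indices: list[int] | None = None,
    azimuth_indices: list[int] | None = None,
    geometry_mode: str = "fixed-z",
    residue_range: tuple[int, int] = (0, 0),
    extracellular_reference_index: int | None = None,
) -> AngleSeries:
    """Evaluate one orientation observable on every frame of *trajectory*.

    The trajectory is expected to be windowed/strided already (see
    :func:`helixmetrics.trajectory_io.select_frames`).

    For ``observable="tilt"``, *ca_indices* (TM Calpha atoms in residue
    order) and *phosphorus_indices* are required; the membrane geometry is
    re-estimated per frame. For ``observable="azimuthal"``,
    *azimuth_indices* must name exactly 4 Calpha atoms.
    """
    times = []
    values = []
    if observable == "tilt":
        if ca_indices is None or phosphorus_indices is None:
            raise ValueError("tilt needs ca_indices and phosphorus_indices")
        for fr in trajectory.frames:
            try:
                ref = (
                    fr.coordinates[extracellular_reference_index]
                    if extracellular_reference_index is not None
                    else fr.coordinates[ca_indices[0]]
                )
                geom = estimate_membrane_geometry(
                    fr, phosphorus_indices, mode=geometry_mode, extracellular_reference=ref
                )
                ax = fit_helix_axis(fr.coordinates, ca_indices, residue_range)
                values.append(tilt_angle(ax, geom))
            except ValueError as exc:
                raise ValueError(f"frame at t={fr.time} ps: {exc}") from exc
            times.append(fr.time)
        return AngleSeries(np.array(times), np.array(values), kind="tilt", wrap=(0.0, 90.0))
    elif observable == "azimuthal":
        if azimuth_indices is None or len(azimuth_indices) != 4:
            raise ValueError("azimuthal needs exactly 4 atom indices")
        for fr in trajectory.frames:
            try:
                p = fr.coordinates[np.asarray(azimuth_indices, int)]
                values.append(torsion_angle(*p))
            except ValueError as exc:
                raise ValueError(f"frame at t={fr.time} ps: {exc}") from exc
            times.append(fr.time)
        return AngleSeries(
            np.array(times), np.array(values), kind="azimuthal", wrap=(-180.0, 180.0)
        )
    raise ValueError(f"unknown observable {observable!r}")


def summarize_angles(series: AngleSeries) -> AngleSummary:
    """Linear and circular summary statistics of an angle series.

    Linear mean/SD are computed on the raw wrapped values (population SD,
    so a single observation has SD 0). The circular mean is the argument
    of the mean resultant vector; the circular SD is the Mardia definition
    ``sqrt(-2 ln R)`` converted to degrees.
    """
    v = series.values
    if v.size < 1:
        raise ValueError("empty angle series")
    rad = np.radians(v)
    R = float(np.abs(np.exp(1j * rad).mean()))
    circ_mean = float(np.degrees(stats.circmean(rad, high=np.pi, low=-np.pi)))
    circ_mean = float(wrap_azimuth(circ_mean))
    circ_sd = float(np.degrees(stats.circstd(rad, high=np.pi, low=-np.pi)))
    return AngleSummary(
        linear_mean=float(v.mean()),
        linear_sd=float(v.std(ddof=0)),
        circular_mean=circ_mean,
        circular_sd=circ_sd,
        resultant_length=R,
        n=int(v.size),
        weakly_concentrated=R < WEAK_CONCENTRATION_R,
    )


def angle_histogram(series: AngleSeries, bin_width: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Normalised density histogram over the series' full wrap range.

    Returns ``(bin_centers, densities)`` with
    ``sum(densities) * bin_width == 1``. Empty bins are included so that
    histograms of different series are directly comparable.
    """
    lo, hi = series.wrap
    span = hi - lo
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin width {bin_width} deg does not divide the wrap range {span} deg"
        )
    n_bins = int(round(n_bins))
    edges = lo + np.arange(n_bins + 1) * bin_width
    # values equal to the lower open edge belong to the top bin on a circle
    counts, _ = np.histogram(np.clip(series.values, lo + 1e-12, hi), bins=edges)
    densities = counts / (series.n * bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, densities
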