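"""Synthetic helix-in-bilayer trajectories with exact ground truth.

Desk-scale stand-in for cluster-scale membrane-protein MD: a rigid ideal
alpha-helix spans a bilayer slab represented by two jittered phosphorus
pseudo-planes (default +/-19 A, approximating POPC phosphate planes);
water oxygens fill the box outside the slab as an ideal gas at bulk
density. Per frame, a tilt angle and an azimuthal rotation are drawn from
configurable angular distributions (von Mises, or uniform for the
azimuth) and applied to the helix as rigid rotations, so every analysis
stage can be checked by parameter recovery against the sampled values.

Ground-truth exactness is engineered into the construction:

* the helix coordinates are pre-aligned so the SVD-fitted Calpha axis is
  exactly the z-axis; the realised tilt then equals the sampled tilt
  (folded to [0, 90]) to floating-point precision;
* four intracellular marker Calpha atoms are placed so that their
  4-point torsion equals the sampled azimuth exactly: the two middle
  markers sit on the rotation axis, the first marker rides the azimuthal
  rotation (but not the tilt), and the last is fixed in the lab frame,
  representing the intracellular domain. At the reference orientation
  both angles are 0.

Rare water-penetration events near a chosen residue (a membrane defect
letting a few waters reach a buried polar side chain) are emulated by a
set of reserved water atoms that jump to within 4 A of that residue's
Cbeta on event frames and sit in the bulk otherwise, keeping the atom
count constant as trajectory formats require.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .trajectory_io import AtomRecord, Frame, Trajectory, write_topology, write_trajectory

__all__ = [
    "AngularDistribution",
    "PenetrationSpec",
    "ICDomainSpec",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticSystem",
    "build_ideal_helix",
    "kappa_from_sd",
    "generate_trajectory",
    "generate_reference_frame",
    "make_variant_panel",
]

BULK_WATER_DENSITY = 0.0334  # waters / A^3 (TIP3P-like bulk)
MIN_WATER_SEPARATION = 2.8  # A, used only for the capacity bound
HELIX_RADIUS = 2.3  # A, Calpha radius of a canonical alpha-helix
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # deg per residue
CB_OFFSET = 1.5  # A, radial Cbeta displacement


@dataclass(frozen=True)
class AngularDistribution:
    """Von Mises (mean, SD) or uniform-on-the-circle angular law, degrees."""

    mean_deg: float = 0.0
    sd_deg: float = 1.0
    uniform: bool = False

    def __post_init__(self) -> None:
        if not self.uniform and self.sd_deg < 0:
            raise ValueError("sd_deg must be >= 0")


@dataclass(frozen=True)
class PenetrationSpec:
    """Rare water-penetration events near one residue's Cbeta."""

    target_residue: int = 505
    probability: float = 0.0  # per-frame event probability
    n_waters_per_event: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.n_waters_per_event < 1:
            raise ValueError("n_waters_per_event must be >= 1")


@dataclass(frozen=True)
class ICDomainSpec:
    """Intracellular markers and Box1-blob placement mode."""

    n_marker_atoms: int = 4
    mode: str = "open"  # "open" (solvent-exposed blob) | "packed" (membrane-buried)

    def __post_init__(self) -> None:
        if self.n_marker_atoms != 4:
            raise ValueError("exactly 4 azimuth marker atoms are supported")
        if self.mode not in ("open", "packed"):
            raise ValueError(f"unknown IC mode {self.mode!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one generated helix-in-bilayer system."""

    n_frames: int = 100
    dt: float = 10.0  # ps between stored frames
    helix_residues: int = 23  # TM span (default mirrors residues 490-512)
    residue_number_start: int = 490
    tilt_distribution: AngularDistribution = field(
        default_factory=lambda: AngularDistribution(mean_deg=27.6, sd_deg=7.0)
    )
    azimuth_distribution: AngularDistribution = field(
        default_factory=lambda: AngularDistribution(mean_deg=0.0, sd_deg=15.0)
    )
    slab_half_thickness: float = 19.0  # A, phosphorus plane |z|
    box: tuple[float, float, float] = (75.0, 75.0, 110.0)  # A
    n_waters: int | None = None  # None: bulk density outside the slab
    penetration: PenetrationSpec = field(default_factory=PenetrationSpec)
    ic_domain: ICDomainSpec = field(default_factory=ICDomainSpec)
    phosphorus_per_leaflet_side: int = 8  # grid side; 8 -> 64 P per leaflet
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.helix_residues < 4:
            raise ValueError("n_frames >= 1 and helix_residues >= 4 required")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.slab_half_thickness <= 0 or any(e <= 0 for e in self.box):
            raise ValueError("slab_half_thickness and box edges must be > 0")

    @property
    def water_region_volume(self) -> float:
        bx, by, bz = self.box
        return bx * by * max(bz - 2 * self.slab_half_thickness, 0.0)

    @property
    def effective_n_waters(self) -> int:
        if self.n_waters is not None:
            return int(self.n_waters)
        return int(round(BULK_WATER_DENSITY * self.water_region_volume))


@dataclass
class GroundTruth:
    """Per-frame sampled angles and realised expectations."""

    tilt_deg: np.ndarray  # signed samples, degrees
    azimuth_deg: np.ndarray  # degrees in (-180, 180]
    realized_tilt_deg: np.ndarray  # |tilt| as the analysis will see it
    penetration_event: np.ndarray  # bool per frame
    penetration_water_indices: list[int]  # topology indices of reserved waters
    expected: dict  # summary stats of the sampled series


@dataclass
class SyntheticSystem:
    """A generated system: topology + trajectory (+ file paths if written)."""

    topology: list[AtomRecord]
    trajectory: Trajectory
    ground_truth: GroundTruth
    spec: SyntheticSpec
    topology_path: str | None = None
    trajectory_path: str | None = None


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------


def build_ideal_helix(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical alpha-helix along +z, centroid at the origin.

    Returns ``(ca, cb)`` arrays of shape (n_residues, 3): Calpha on a
    2.3 A-radius cylinder rising 1.5 A and twisting 100 deg per residue,
    Cbeta displaced 1.5 A radially outward from each Calpha.
    """
    if n_residues < 4:
        raise ValueError(f"need >= 4 residues, got {n_residues}")
    k = np.arange(n_residues)
    phase = np.radians(HELIX_TWIST * k)
    ca = np.column_stack(
        [HELIX_RADIUS * np.cos(phase), HELIX_RADIUS * np.sin(phase), HELIX_RISE * k]
    )
    radial = np.column_stack([np.cos(phase), np.sin(phase), np.zeros_like(phase)])
    cb = ca + CB_OFFSET * radial
    shift = ca.mean(axis=0)
    return ca - shift, cb - shift


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _rot_x(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _aligned_tm_coordinates(n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """TM helix at the reference orientation.

    The first (lowest-numbered, extracellular) residue is at the top, so
    the first->last axis points along -z; the coordinates are pre-rotated
    so the SVD-fitted Calpha axis is exactly +/-z, making the realised
    tilt equal the applied tilt rotation with no estimator offset.
    """
    ca, cb = build_ideal_helix(n_residues)
    flip = _rot_x(180.0)  # residue index now descends in z
    ca = ca @ flip.T
    cb = cb @ flip.T
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0] / np.linalg.norm(vt[0])
    if axis[2] > 0:
        axis = -axis  # first -> last points down
    align = _rotation_aligning(axis, np.array([0.0, 0.0, -1.0]))
    return ca @ align.T, cb @ align.T


def _marker_reference(helix_bottom_z: float) -> np.ndarray:
    """Reference positions of the 4 azimuth marker Calpha atoms.

    p2 and p3 sit on the z-axis, p1 (attached to the rotating TM body)
    and p4 (fixed, intracellular) both at x=+3; the torsion p1-p2-p3-p4
    is 0 here and equals the azimuthal rotation applied to p1.
    """
    b = helix_bottom_z
    return np.array(
        [
            [3.0, 0.0, b - 9.5],
            [0.0, 0.0, b - 11.5],
            [0.0, 0.0, b - 14.5],
            [3.0, 0.0, b - 16.5],
        ]
    )


def _box1_reference(mode: str, rng: np.random.Generator) -> np.ndarray:
    """Static 4-atom Box1 blob: solvent-exposed ("open") or slab-buried."""
    z_center = -26.0 if mode == "open" else -14.5
    base = np.array(
        [
            [10.0, 2.0, z_center],
            [12.0, 0.0, z_center - 1.0],
            [10.0, -2.0, z_center + 0.5],
            [8.0, 0.0, z_center - 0.5],
        ]
    )
    return base + rng.uniform(-0.4, 0.4, size=base.shape)


def kappa_from_sd(sd_deg: float) -> float:
    """Von Mises concentration whose circular SD equals *sd_deg*.

    Solves ``sqrt(-2 ln(I1(k)/I0(k))) = sd`` (radians) for k; for the
    small SDs used here this makes the linear SD of the samples match the
    request to well under 0.1 deg.
    """
    sd_rad = np.radians(sd_deg)
    if sd_rad <= 0:
        raise ValueError("sd must be > 0 for a von Mises draw")
    r_target = float(np.exp(-0.5 * sd_rad**2))

    def f(kappa: float) -> float:
        return i1e(kappa) / i0e(kappa) - r_target

    return float(brentq(f, 1e-8, 1e8, xtol=1e-12, rtol=1e-12))


def _sample_angles(dist: AngularDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist.uniform:
        return rng.uniform(-180.0, 180.0, size=n)
    if dist.sd_deg == 0:
        return np.full(n, dist.mean_deg)
    kappa = kappa_from_sd(dist.sd_deg)
    draws = rng.vonmises(np.radians(dist.mean_deg), kappa, size=n)
    return np.degrees(draws)


# ---------------------------------------------------------------------------
# topology and frames
# ---------------------------------------------------------------------------


def _build_topology(spec: SyntheticSpec) -> tuple[list[AtomRecord], dict]:
    """Atom records plus an index map naming every structural block."""
    records: list[AtomRecord] = []
    idx: dict = {"ca": [], "cb": [], "marker": [], "box1": [], "phosphorus": [], "water": []}
    i = 0
    r0 = spec.residue_number_start
    for k in range(spec.helix_residues):
        resid = r0 + k
        records.append(AtomRecord(i, "CA", resid, "ALA", "PROT", "C"))
        idx["ca"].append(i)
        i += 1
        records.append(AtomRecord(i, "CB", resid, "ALA", "PROT", "C"))
        idx["cb"].append(i)
        i += 1
    marker_resid0 = r0 + spec.helix_residues + 8  # small gap below the TM span
    for k in range(4):
        records.append(AtomRecord(i, "CA", marker_resid0 + k, "GLY", "ICDM", "C"))
        idx["marker"].append(i)
        i += 1
    box1_resid0 = marker_resid0 + 4
    for k in range(4):
        records.append(AtomRecord(i, "CA", box1_resid0 + k, "GLY", "BOX1", "C"))
        idx["box1"].append(i)
        i += 1
    n_side = spec.phosphorus_per_leaflet_side
    n_p = 2 * n_side * n_side
    for k in range(n_p):
        records.append(AtomRecord(i, "P", 1000 + k, "POP", "MEMB", "P"))
        idx["phosphorus"].append(i)
        i += 1
    n_w = spec.effective_n_waters
    n_reserved = spec.penetration.n_waters_per_event if spec.penetration.probability > 0 else 0
    for k in range(n_w + n_reserved):
        records.append(AtomRecord(i, "OH2", 2000 + k, "TIP3", "WAT", "O"))
        idx["water"].append(i)
        i += 1
    idx["reserved_water"] = idx["water"][n_w:]
    idx["marker_resid0"] = marker_resid0
    idx["box1_resid0"] = box1_resid0
    return records, idx


def _phosphorus_grid(spec: SyntheticSpec) -> np.ndarray:
    """Static xy grid of phosphorus sites for both leaflets (z set later)."""
    n = spec.phosphorus_per_leaflet_side
    bx, by, _ = spec.box
    xs = (np.arange(n) + 0.5) / n * bx - bx / 2
    ys = (np.arange(n) + 0.5) / n * by - by / 2
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _sample_bulk_waters(n: int, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform water-oxygen positions in the box outside the slab."""
    bx, by, bz = spec.box
    h = spec.slab_half_thickness
    xy = rng.uniform([-bx / 2, -by / 2], [bx / 2, by / 2], size=(n, 2))
    top_height = bz / 2 - h
    u = rng.uniform(0.0, 1.0, size=n)
    sign = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
    z = sign * (h + u * top_height)
    return np.column_stack([xy, z])


def structural_indices(spec: SyntheticSpec) -> dict:
    """Atom-index map of a generated system's structural blocks.

    Keys: ``ca``, ``cb`` (TM helix, residue order), ``marker`` (the 4
    azimuth Calpha markers), ``box1``, ``phosphorus``, ``water``,
    ``reserved_water``.
    """
    return _build_topology(spec)[1]


def generate_reference_frame(spec: SyntheticSpec) -> tuple[list[AtomRecord], Frame, dict]:
    """The initial-placement construction: no rotations, no waters moved.

    Helix axis along the bilayer normal (tilt 0) and markers at their
    calibration positions (azimuth 0). Returned as (topology, frame,
    index map); water positions are drawn from the spec's seed.
    """
    frozen = SyntheticSpec(**{**asdict_spec(spec), "n_frames": 1,
                              "tilt_distribution": AngularDistribution(0.0, 0.0),
                              "azimuth_distribution": AngularDistribution(0.0, 0.0)})
    system = generate_trajectory(frozen)
    return system.topology, system.trajectory.frames[0], _build_topology(frozen)[1]


def asdict_spec(spec: SyntheticSpec) -> dict:
    """Spec as a plain dict with nested dataclasses preserved."""
    d = asdict(spec)
    d["tilt_distribution"] = spec.tilt_distribution
    d["azimuth_distribution"] = spec.azimuth_distribution
    d["penetration"] = spec.penetration
    d["ic_domain"] = spec.ic_domain
    d["box"] = tuple(spec.box)
    return d


def generate_trajectory(
    spec: SyntheticSpec, out_dir: str | os.PathLike | None = None, label: str = "system"
) -> SyntheticSystem:
    """Generate a full synthetic system; optionally write PDB + DCD files.

    Fully reproducible from ``spec.seed``; identical specs give
    byte-identical files. With ``out_dir=None`` the system is returned
    in memory only.
    """
    n_w = spec.effective_n_waters
    n_reserved = spec.penetration.n_waters_per_event if spec.penetration.probability > 0 else 0
    capacity = spec.water_region_volume / MIN_WATER_SEPARATION**3
    if n_w + n_reserved > capacity:
        raise ValueError(
            f"{n_w + n_reserved} waters exceed the box capacity "
            f"(~{int(capacity)}) at {MIN_WATER_SEPARATION} A separation"
        )
    rng = np.random.default_rng(spec.seed)
    topology, idx = _build_topology(spec)
    ca0, cb0 = _aligned_tm_coordinates(spec.helix_residues)
    helix_bottom = ca0[:, 2].min()
    markers0 = _marker_reference(helix_bottom)
    box1 = _box1_reference(spec.ic_domain.mode, rng)
    p_xy = _phosphorus_grid(spec)
    n_p_leaflet = p_xy.shape[0]
    box = np.asarray(spec.box, float)

    tilt = _sample_angles(spec.tilt_distribution, spec.n_frames, rng)
    azim = _sample_angles(spec.azimuth_distribution, spec.n_frames, rng)
    events = rng.uniform(size=spec.n_frames) < spec.penetration.probability

    target_cb = None
    if n_reserved:
        t_off = spec.penetration.target_residue - spec.residue_number_start
        if not 0 <= t_off < spec.helix_residues:
            raise ValueError(
                f"penetration target residue {spec.penetration.target_residue} "
                f"outside the helix span"
            )
        target_cb = t_off  # row index into cb coordinates

    n_atoms = len(topology)
    frames: list[Frame] = []
    for i in range(spec.n_frames):
        coords = np.empty((n_atoms, 3))
        rz = _rot_z(azim[i])
        rx = _rot_x(tilt[i])
        body = rx @ rz
        coords[idx["ca"]] = ca0 @ body.T
        coords[idx["cb"]] = cb0 @ body.T
        m = markers0.copy()
        m[0] = rz @ markers0[0]  # p1 rides the azimuthal rotation only
        coords[idx["marker"]] = m
        coords[idx["box1"]] = box1
        z_jit = rng.uniform(-0.5, 0.5, size=2 * n_p_leaflet)
        p = np.empty((2 * n_p_leaflet, 3))
        p[:, :2] = np.vstack([p_xy, p_xy])
        p[:n_p_leaflet, 2] = spec.slab_half_thickness + z_jit[:n_p_leaflet]
        p[n_p_leaflet:, 2] = -spec.slab_half_thickness + z_jit[n_p_leaflet:]
        coords[idx["phosphorus"]] = p
        waters = _sample_bulk_waters(n_w + n_reserved, spec, rng)
        if n_reserved and events[i]:
            cb_pos = coords[idx["cb"][target_cb]]
            # uniform in a 2.6-4.0 A shell around the target Cbeta
            u = rng.uniform(size=n_reserved)
            r = (2.6**3 + u * (4.0**3 - 2.6**3)) ** (1.0 / 3.0)
            v = rng.normal(size=(n_reserved, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            waters[n_w:] = cb_pos + r[:, None] * v
        coords[idx["water"]] = waters
        frames.append(Frame(coords, time=(i + 1) * spec.dt, box=box.copy()))

    trajectory = Trajectory(topology=topology, frames=frames, nominal_dt=spec.dt)
    realized = np.abs(tilt)
    expected = {
        "tilt_mean": float(realized.mean()),
        "tilt_sd": float(realized.std(ddof=0)),
        "azimuth_circular_mean": _circ_mean_deg(azim),
        "azimuth_resultant_length": _resultant_length(azim),
        "n_frames": spec.n_frames,
        "penetration_event_count": int(events.sum()),
    }
    gt = GroundTruth(
        tilt_deg=tilt,
        azimuth_deg=azim,
        realized_tilt_deg=realized,
        penetration_event=events,
        penetration_water_indices=list(idx["reserved_water"]),
        expected=expected,
    )
    system = SyntheticSystem(topology=topology, trajectory=trajectory, ground_truth=gt, spec=spec)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        top_path = os.path.join(out_dir, f"{label}.pdb")
        trj_path = os.path.join(out_dir, f"{label}.dcd")
        write_topology(top_path, topology, frames[0].coordinates, box=box)
        write_trajectory(trj_path, trajectory)
        system.topology_path = top_path
        system.trajectory_path = trj_path
    return system


def _circ_mean_deg(deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(deg)).mean()
    return float(np.degrees(np.angle(z)))


def _resultant_length(deg: np.ndarray) -> float:
    return float(np.abs(np.exp(1j * np.radians(deg)).mean()))


def make_variant_panel(
    specs: list[tuple[str, SyntheticSpec]], out_dir: str | os.PathLike
) -> dict:
    """Generate one system per labelled spec; write files and a manifest.

    The manifest (``manifest.json`` in *out_dir*) records, per variant,
    the file paths and the ground-truth summary statistics of the sampled
    angle series, for downstream recovery checks.
    """
    if not specs:
        raise ValueError("need at least one labelled spec")
    labels = [lab for lab, _ in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels in panel: {labels}")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"variants": {}}
    for label, spec in specs:
        system = generate_trajectory(spec, out_dir=out_dir, label=label)
        manifest["variants"][label] = {
            "topology": os.path.basename(system.topology_path),
            "trajectory": os.path.basename(system.trajectory_path),
            "n_frames": spec.n_frames,
            "dt_ps": spec.dt,
            "seed": spec.seed,
            "ground_truth": system.ground_truth.expected,
        }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["path"] = path
    return manifest
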