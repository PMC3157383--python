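"""Config-driven end-to-end analysis of a panel of variant trajectories.

Applies the analysis conventions used throughout this package to each
variant of a panel — window the trajectory (default: the last 100 ns),
stride it (10 ps for angle series, 100 ps for azimuth histograms),
compute tilt and azimuth series, water RDFs around the key residues, and
intracellular region metrics — and writes paper-style report tables
(tilt table, azimuth table with histograms, RDF curves, region metrics).

Analysis is deterministic: identical inputs give byte-identical outputs.
Every applied default and every selection's resolved atom count is
logged, which is the main guard against silent residue-numbering
mismatches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import conformation_metrics as cm
from . import helix_orientation as ho
from . import hydration_rdf as hr
from . import membrane_geometry as mg
from . import trajectory_io as tio

__all__ = ["VariantInput", "RunConfig", "Report", "load_config", "run_analysis", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantInput:
    label: str
    topology: str
    trajectory: str


@dataclass(frozen=True)
class AtomSpecifier:
    """Names exactly one atom: residue number + atom name (+ segment)."""

    residue_number: int
    atom_name: str = "CA"
    segment_id: str | None = None

    def resolve(self, topology: list[tio.AtomRecord]) -> int:
        spec = tio.SelectionSpec(
            atom_names=frozenset({self.atom_name}),
            residue_range=(self.residue_number, self.residue_number),
            segment_id=self.segment_id,
        )
        idx = tio.select_atoms(topology, spec)
        if len(idx) != 1:
            raise ValueError(
                f"atom specifier {self} resolves to {len(idx)} atoms (need exactly 1)"
            )
        return idx[0]


@dataclass
class RunConfig:
    """Full parameterisation of one panel analysis run."""

    variants: list[VariantInput]
    tm_residues: tuple[int, int] = (490, 512)
    key_residues: tuple[int, ...] = (491, 505, 515)
    azimuth_quad: list[AtomSpecifier] = field(default_factory=list)
    regions: list[cm.RegionDefinition] = field(default_factory=list)
    window_last_ps: float | None = 100_000.0  # "last N ns" convention
    window: tuple[float, float] | None = None  # explicit (start, end] ps
    angle_stride_ps: float = 10.0
    azimuth_histogram_stride_ps: float = 100.0
    azimuth_bin_width_deg: float = 10.0
    rdf_r_max: float = 15.0
    rdf_bin_width: float = 0.1
    rdf_normalization: str = "box-density"
    geometry_mode: str = "fixed-z"
    exposure_cutoff: float = cm.DEFAULT_EXPOSURE_CUTOFF
    water_atom_names: tuple[str, ...] = tuple(sorted(tio.DEFAULT_WATER_ATOM_NAMES))
    water_residue_names: tuple[str, ...] = tuple(sorted(tio.DEFAULT_WATER_RESIDUE_NAMES))

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("need at least one variant")
        paths = [(v.topology, v.trajectory) for v in self.variants]
        if len(set(paths)) != len(paths):
            raise ValueError("variant input paths must be distinct")
        if self.window is None and self.window_last_ps is None:
            raise ValueError("either window or window_last_ps must be given")


@dataclass
class Report:
    """In-memory result tables; one entry per variant in every table."""

    tilt_table: dict[str, dict[str, float]]
    azimuth_table: dict[str, dict[str, Any]]
    rdf_curves: dict[str, dict[str, dict[str, list[float]]]]  # variant -> residue -> curve
    region_metrics: dict[str, dict[str, dict[str, float]]]  # variant -> region -> summary


def load_config(path: str | os.PathLike) -> RunConfig:
    """Read a YAML run configuration (see docs for the schema)."""
    with open(os.fspath(path)) as fh:
        raw = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(os.fspath(path)))

    def _p(rel: str) -> str:
        return rel if os.path.isabs(rel) else os.path.join(base, rel)

    variants = [
        VariantInput(v["label"], _p(v["topology"]), _p(v["trajectory"]))
        for v in raw["variants"]
    ]
    kwargs: dict[str, Any] = {"variants": variants}
    if "tm_residues" in raw:
        kwargs["tm_residues"] = tuple(raw["tm_residues"])
    if "key_residues" in raw:
        kwargs["key_residues"] = tuple(raw["key_residues"])
    if "azimuth_quad" in raw:
        kwargs["azimuth_quad"] = [
            AtomSpecifier(
                residue_number=a["residue_number"],
                atom_name=a.get("atom_name", "CA"),
                segment_id=a.get("segment_id"),
            )
            for a in raw["azimuth_quad"]
        ]
    if "regions" in raw:
        kwargs["regions"] = [
            cm.RegionDefinition(
                label=r["label"],
                residue_range=tuple(r["residue_range"]),
                atom_scope=r.get("atom_scope", "heavy-atoms"),
                numbering_offset=r.get("numbering_offset", 0),
            )
            for r in raw["regions"]
        ]
    win = raw.get("window")
    if isinstance(win, dict):
        kwargs["window"] = (float(win["start_ps"]), float(win["end_ps"]))
        kwargs["window_last_ps"] = None
    elif isinstance(win, str):
        # "last 100 ns" / "last 100000 ps"
        parts = win.split()
        if len(parts) != 3 or parts[0] != "last" or parts[2] not in ("ns", "ps"):
            raise ValueError(f"cannot parse window {win!r}; use 'last <N> ns|ps'")
        n = float(parts[1])
        kwargs["window_last_ps"] = n * 1000.0 if parts[2] == "ns" else n
    strides = raw.get("strides", {})
    if "angles" in strides:
        kwargs["angle_stride_ps"] = float(strides["angles"])
    if "azimuth_histogram" in strides:
        kwargs["azimuth_histogram_stride_ps"] = float(strides["azimuth_histogram"])
    rdf = raw.get("rdf", {})
    for src, dst in (("r_max", "rdf_r_max"), ("bin_width", "rdf_bin_width"),
                     ("normalization", "rdf_normalization")):
        if src in rdf:
            kwargs[dst] = rdf[src]
    for key in ("geometry_mode", "exposure_cutoff", "azimuth_bin_width_deg"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _window_bounds(cfg: RunConfig, trajectory: tio.Trajectory) -> tuple[float, float]:
    if cfg.window is not None:
        return cfg.window
    start, end = tio.last_n_window(trajectory, cfg.window_last_ps)
    logger.info("window default applied: last %g ps -> (%g, %g]", cfg.window_last_ps, start, end)
    return start, end


def _analyze_variant(cfg: RunConfig, variant: VariantInput) -> dict[str, Any]:
    topology = tio.read_topology(variant.topology)
    trj = tio.read_trajectory(topology, variant.trajectory, topology_path=variant.topology)
    logger.info("%s: %d atoms, %d frames, dt=%g ps",
                variant.label, trj.n_atoms, trj.n_frames, trj.nominal_dt)

    ca_idx = tio.select_atoms(
        topology, tio.SelectionSpec(atom_names=frozenset({"CA"}), residue_range=cfg.tm_residues)
    )
    p_idx = tio.select_atoms(topology, tio.SelectionSpec(atom_names=frozenset({"P"})))
    water_idx = tio.select_water_oxygens(
        topology, cfg.water_atom_names, cfg.water_residue_names
    )
    logger.info("%s: selections resolved: %d TM Calpha, %d phosphorus, %d water oxygens",
                variant.label, len(ca_idx), len(p_idx), len(water_idx))
    if not ca_idx:
        raise ValueError(f"{variant.label}: TM Calpha selection {cfg.tm_residues} is empty")
    if not p_idx:
        raise ValueError(f"{variant.label}: phosphorus selection is empty")

    start, end = _window_bounds(cfg, trj)
    angle_trj = tio.select_frames(trj, start, end, cfg.angle_stride_ps)
    hist_trj = tio.select_frames(trj, start, end, cfg.azimuth_histogram_stride_ps)

    tilt = ho.angle_series(
        angle_trj, "tilt", ca_indices=ca_idx, phosphorus_indices=p_idx,
        geometry_mode=cfg.geometry_mode, residue_range=cfg.tm_residues,
    )
    tilt_summary = ho.summarize_angles(tilt)

    out: dict[str, Any] = {
        "tilt": {
            "mean": tilt_summary.linear_mean,
            "sd": tilt_summary.linear_sd,
            "n": tilt_summary.n,
        }
    }

    if cfg.azimuth_quad:
        quad = [a.resolve(topology) for a in cfg.azimuth_quad]
        az = ho.angle_series(angle_trj, "azimuthal", azimuth_indices=quad)
        az_hist_series = ho.angle_series(hist_trj, "azimuthal", azimuth_indices=quad)
        azs = ho.summarize_angles(az)
        centers, dens = ho.angle_histogram(az_hist_series, cfg.azimuth_bin_width_deg)
        out["azimuth"] = {
            "circular_mean": azs.circular_mean,
            "linear_mean": azs.linear_mean,
            "circular_sd": azs.circular_sd,
            "resultant_length": azs.resultant_length,
            "weakly_concentrated": azs.weakly_concentrated,
            "n": azs.n,
            "histogram_bin_centers": centers.tolist(),
            "histogram_densities": dens.tolist(),
            "histogram_n": az_hist_series.n,
        }

    rdfs: dict[str, dict[str, list[float]]] = {}
    if water_idx:
        for resid in cfg.key_residues:
            cb = tio.select_atoms(
                topology,
                tio.SelectionSpec(atom_names=frozenset({"CB"}), residue_range=(resid, resid)),
            )
            if len(cb) != 1:
                logger.warning("%s: residue %d has %d CB atoms; RDF skipped",
                               variant.label, resid, len(cb))
                continue
            rdf = hr.water_rdf(
                angle_trj, cb[0], water_idx, r_max=cfg.rdf_r_max,
                bin_width=cfg.rdf_bin_width, normalization=cfg.rdf_normalization,
                center_label=f"CB {resid}",
            )
            rdfs[str(resid)] = {
                "r_mid": rdf.bin_centers.tolist(),
                "g": rdf.g_values.tolist(),
                "coordination_4A": hr.coordination_number(rdf, 4.0),
            }
    out["rdf"] = rdfs

    regions: dict[str, dict[str, float]] = {}
    if cfg.regions and water_idx:
        geometries = [
            mg.estimate_membrane_geometry(
                fr, p_idx, mode=cfg.geometry_mode,
                extracellular_reference=fr.coordinates[ca_idx[0]],
            )
            for fr in angle_trj.frames
        ]
        for region in cfg.regions:
            series = cm.region_metric_series(
                angle_trj, region, geometries, water_idx, cfg.exposure_cutoff
            )
            regions[region.label] = {
                "mean_min_membrane_distance": float(series.min_membrane_distance.mean()),
                "mean_exposure": float(series.hydration_count.mean()),
                "n": int(series.times.size),
            }
    out["regions"] = regions
    return out


def run_analysis(cfg: RunConfig, keep_going: bool = False) -> Report:
    """Run the full analysis for every configured variant.

    A failing variant aborts the run with an error naming it, unless
    *keep_going* is set, in which case it is dropped from the report
    (logged as an error).
    """
    tilt_table: dict[str, dict[str, float]] = {}
    azimuth_table: dict[str, dict[str, Any]] = {}
    rdf_curves: dict[str, dict[str, dict[str, list[float]]]] = {}
    region_metrics: dict[str, dict[str, dict[str, float]]] = {}
    for variant in cfg.variants:
        try:
            res = _analyze_variant(cfg, variant)
        except Exception as exc:
            if keep_going:
                logger.error("variant %s failed, continuing: %s", variant.label, exc)
                continue
            raise RuntimeError(f"variant {variant.label!r} failed: {exc}") from exc
        tilt_table[variant.label] = res["tilt"]
        if "azimuth" in res:
            azimuth_table[variant.label] = res["azimuth"]
        rdf_curves[variant.label] = res["rdf"]
        region_metrics[variant.label] = res["regions"]
    return Report(
        tilt_table=tilt_table,
        azimuth_table=azimuth_table,
        rdf_curves=rdf_curves,
        region_metrics=region_metrics,
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(report: Report, out_dir: str | os.PathLike, formats: tuple[str, ...] = ("tsv", "json")) -> dict:
    """Write report tables to *out_dir*; returns a checksummed manifest.

    Angle tables are formatted to 1 decimal (TSV), g(r) to 4 decimals;
    the JSON report keeps full precision.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    if "tsv" in formats:
        path = os.path.join(out_dir, "tilt_table.tsv")
        with open(path, "w") as fh:
            fh.write("variant\tmean_deg\tsd_deg\tn\n")
            for label, row in report.tilt_table.items():
                fh.write(f"{label}\t{row['mean']:.1f}\t{row['sd']:.1f}\t{row['n']}\n")
        written.append(path)
        if report.azimuth_table:
            path = os.path.join(out_dir, "azimuth_table.tsv")
            with open(path, "w") as fh:
                fh.write("variant\tcircular_mean_deg\tlinear_mean_deg\tresultant_length\tweakly_concentrated\tn\n")
                for label, row in report.azimuth_table.items():
                    fh.write(
                        f"{label}\t{row['circular_mean']:.1f}\t{row['linear_mean']:.1f}\t"
                        f"{row['resultant_length']:.3f}\t{row['weakly_concentrated']}\t{row['n']}\n"
                    )
            written.append(path)
        for label, curves in report.rdf_curves.items():
            for resid, curve in curves.items():
                path = os.path.join(out_dir, f"rdf_{label}_res{resid}.tsv")
                with open(path, "w") as fh:
                    fh.write("r_mid_A\tg\n")
                    for r, g in zip(curve["r_mid"], curve["g"]):
                        fh.write(f"{r:.2f}\t{g:.4f}\n")
                written.append(path)
        if any(report.region_metrics.values()):
            path = os.path.join(out_dir, "region_metrics.tsv")
            with open(path, "w") as fh:
                fh.write("variant\tregion\tmean_min_membrane_distance_A\tmean_exposure\tn\n")
                for label, regions in report.region_metrics.items():
                    for rlabel, row in regions.items():
                        fh.write(
                            f"{label}\t{rlabel}\t{row['mean_min_membrane_distance']:.2f}\t"
                            f"{row['mean_exposure']:.2f}\t{row['n']}\n"
                        )
            written.append(path)

    if "json" in formats:
        path = os.path.join(out_dir, "report.json")
        payload = {
            "tilt_table": report.tilt_table,
            "azimuth_table": report.azimuth_table,
            "rdf_curves": report.rdf_curves,
            "region_metrics": report.region_metrics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        written.append(path)

    manifest = {
        "files": [
            {"path": os.path.basename(p), "sha256": _sha256(p)} for p in sorted(written)
        ]
    }
    manifest_path = os.path.join(out_dir, "report_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["path"] = manifest_path
    return manifest
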