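"""Readers, writers, configuration, and the end-to-end pipeline driver.

File conventions: TIFF for image stacks (one multi-page stack per
polarization channel, 16-bit) with a JSON metadata sidecar; CSV for
tabular outputs (traces, localizations, dwell statistics, FSC curves);
JSON for structured results (particles, fit reports, configs); MRC/CCP4
for voxelized densities so reconstructions open directly in EM viewers.
Distances are nm throughout; angles are degrees in files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .localize import FluorophorePosition, Particle2D
from .simkit import (DEFAULT_OPTICS, ImageStackPair, OpticsConfig, PRESETS,
                     build_heptamer_model, build_nanoruler_model,
                     load_point_model, make_scene, render_stack)

__all__ = [
    "PipelineConfig",
    "read_stack_pair",
    "write_stack_pair",
    "write_localizations",
    "read_localizations",
    "write_particles",
    "read_particles",
    "write_mrc",
    "read_mrc",
    "write_fsc_curve",
    "run_pipeline",
]

_REQUIRED_METADATA = ("pixel_size_nm", "frame_time_s", "wavelength_nm",
                      "numerical_aperture")


# --------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything a reproducible pipeline run needs, YAML round-trippable."""

    seed: int = 0
    out_dir: str = "spcold_out"
    model: str = "nanoruler"            # heptamer | nanoruler | path
    model_param_nm: float | None = None   # nn distance / separation
    preset: str = "8K"
    n_particles: int = 3
    n_frames: int = 4000
    fov_px: int = 32
    optics: dict = field(default_factory=lambda: DEFAULT_OPTICS.to_metadata())
    estimator: str = "cos2"
    orientation: str = "membrane"       # uniform | membrane | identity
    tilt_sd_deg: float = 15.0
    min_states: int = 2
    max_extent_nm: float = 40.0
    min_on_frames: int = 20
    brightness_keep: float = 0.8
    segment_unit: str = "event"
    reconstruct: bool = False

    def __post_init__(self):
        if self.n_frames <= 0 or self.n_particles <= 0:
            raise ValueError("sizes must be positive")
        if self.max_extent_nm <= 0 or self.min_states < 1:
            raise ValueError("thresholds must be positive")

    def optics_config(self) -> OpticsConfig:
        return OpticsConfig(**self.optics)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def point_model(self):
        if self.model == "heptamer":
            return build_heptamer_model(self.model_param_nm or 3.5)
        if self.model == "nanoruler":
            return build_nanoruler_model(self.model_param_nm or 30.0)
        return load_point_model(self.model)


# --------------------------------------------------------------------------
# stacks


def write_stack_pair(pair: ImageStackPair, out_dir,
                     seed: int | None = None) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    px = np.clip(pair.stack_x, 0, 65535).astype(np.uint16)
    py = np.clip(pair.stack_y, 0, 65535).astype(np.uint16)
    tifffile.imwrite(out / "channel_x.tif", px)
    tifffile.imwrite(out / "channel_y.tif", py)
    meta = dict(pair.optics.to_metadata())
    meta.update(pair.metadata)
    if seed is not None:
        meta["seed"] = seed
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return {"stack_x": str(out / "channel_x.tif"),
            "stack_y": str(out / "channel_y.tif"),
            "metadata": str(out / "metadata.json")}


def read_stack_pair(path_x, path_y, metadata) -> ImageStackPair:
    """Load and validate a registered two-channel stack.

    ``metadata`` is a dict or a JSON path; the acquisition fields
    pixel_size_nm / frame_time_s / wavelength_nm / numerical_aperture are
    required and missing ones are reported by name.
    """
    sx = tifffile.imread(path_x)
    sy = tifffile.imread(path_y)
    sx = sx[None] if sx.ndim == 2 else sx
    sy = sy[None] if sy.ndim == 2 else sy
    if sx.shape != sy.shape:
        raise ValueError(
            f"channel stacks disagree: {sx.shape} vs {sy.shape}")
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    missing = [k for k in _REQUIRED_METADATA if k not in metadata]
    if missing:
        raise ValueError("metadata missing required fields: "
                         + ", ".join(missing))
    optics = OpticsConfig(
        wavelength_nm=metadata["wavelength_nm"],
        numerical_aperture=metadata["numerical_aperture"],
        pixel_size_nm=metadata["pixel_size_nm"],
        frame_time_s=metadata["frame_time_s"],
        background_rate=metadata.get("background_rate", 0.0))
    return ImageStackPair(sx.astype(np.float32), sy.astype(np.float32),
                          optics, dict(metadata))


# --------------------------------------------------------------------------
# tables


def write_localizations(positions, path) -> None:
    """Positions: sequence of (spot_id, FluorophorePosition) or particles."""
    rows = []
    for spot_id, pos in positions:
        rows.append({"spot_id": spot_id, "state": pos.state_label,
                     "x_nm": pos.x_nm, "y_nm": pos.y_nm,
                     "precision_nm": pos.precision_nm,
                     "n_events": pos.n_events,
                     "photons": pos.total_photons})
    pd.DataFrame(rows, columns=["spot_id", "state", "x_nm", "y_nm",
                                "precision_nm", "n_events", "photons"]
                 ).to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"spot_id", "state", "x_nm", "y_nm", "precision_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    return df


def write_particles(particles, path) -> None:
    payload = []
    for p in particles:
        payload.append({
            "particle_id": p.particle_id,
            "pass_filters": bool(p.pass_filters),
            "reject_reason": p.reject_reason,
            "max_pairwise_nm": p.max_pairwise_nm,
            "positions": [{
                "state": q.state_label, "x_nm": q.x_nm, "y_nm": q.y_nm,
                "precision_x_nm": q.precision_x_nm,
                "precision_y_nm": q.precision_y_nm,
                "n_events": q.n_events, "photons": q.total_photons,
            } for q in p.positions],
        })
    Path(path).write_text(json.dumps(payload, indent=2))


def read_particles(path) -> list:
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        positions = [FluorophorePosition(
            q["state"], q["x_nm"], q["y_nm"], q["precision_x_nm"],
            q["precision_y_nm"], q["n_events"], q["photons"])
            for q in item["positions"]]
        out.append(Particle2D(item["particle_id"], positions,
                              item["max_pairwise_nm"],
                              item["pass_filters"],
                              item.get("reject_reason")))
    return out


def write_fsc_curve(curve, path) -> None:
    pd.DataFrame({
        "frequency_per_nm": curve.shell_frequencies,
        "fsc": curve.correlation,
        "halfbit_threshold": curve.halfbit_threshold,
        "n_voxels": curve.n_voxels_per_shell,
    }).to_csv(path, index=False)


# --------------------------------------------------------------------------
# MRC maps (via gemmi)


def write_mrc(volume: np.ndarray, voxel_nm: float, path) -> None:
    import gemmi

    vol = np.ascontiguousarray(np.asarray(volume, dtype=np.float32))
    grid = gemmi.FloatGrid(*vol.shape)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    # MRC headers are conventionally in angstrom
    a = vol.shape[0] * voxel_nm * 10.0
    b = vol.shape[1] * voxel_nm * 10.0
    c = vol.shape[2] * voxel_nm * 10.0
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90, 90, 90))
    np.asarray(grid, dtype=np.float32)[...] = vol
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> tuple[np.ndarray, float]:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    vol = np.array(m.grid, copy=True)
    voxel_nm = m.grid.unit_cell.a / m.grid.nu / 10.0
    return vol, voxel_nm


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> traces -> localize (-> fit / reconstruct) in one call.

    Each simulated particle is rendered into its own small field of view,
    processed independently (spot detection, polarization-state
    segmentation, per-state localization, particle filters), and the
    surviving particles feed the geometry stage: a projected-distance fit
    for two-label models, or (optionally) a class 3D reconstruction.
    Returns a machine-readable summary; all outputs land in
    ``config.out_dir``.
    """
    from . import localize as loc
    from . import projgeom
    from . import traces as tr

    rng = np.random.default_rng(config.seed)
    optics = config.optics_config()
    model = config.point_model()
    preset = PRESETS[config.preset]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    duration = config.n_frames * optics.frame_time_s
    fov_nm = config.fov_px * optics.pixel_size_nm
    center = (fov_nm / 2.0, fov_nm / 2.0)

    log = {"stages": []}
    particles = []
    all_positions = []
    for pid in range(config.n_particles):
        scene = make_scene(model, preset, duration, rng,
                           position_nm=center,
                           orientation=config.orientation,
                           tilt_sd_deg=config.tilt_sd_deg,
                           frame_time_s=optics.frame_time_s)
        pair = render_stack([scene], optics, config.n_frames,
                            (config.fov_px, config.fov_px), rng)
        spots = tr.detect_spots(pair, min_photons=100)
        if spots.shape[0] == 0:
            continue
        spot = spots[np.argmin(((spots
                                 - np.array(center) / optics.pixel_size_nm)
                                ** 2).sum(1))]
        trace = tr.extract_trace(pair, spot, spot_id=pid,
                                 estimator=config.estimator)
        if config.segment_unit == "event":
            trace = trace.bright_subset()
        if int(trace.on_mask.sum()) < config.min_on_frames:
            continue
        try:
            assignment = tr.segment_polarization_states(
                trace, min_on_frames=config.min_on_frames,
                unit=config.segment_unit)
        except ValueError:
            continue
        positions = loc.localize_states(
            pair, trace, assignment,
            brightness_keep=config.brightness_keep)
        particle = loc.assemble_particle(
            positions, particle_id=pid, min_states=config.min_states,
            max_extent_nm=config.max_extent_nm)
        particles.append(particle)
        all_positions.extend((pid, q) for q in positions)

    write_localizations(all_positions, out / "localizations.csv")
    write_particles(particles, out / "particles.json")
    accepted = [p for p in particles if p.pass_filters]
    log["n_simulated"] = config.n_particles
    log["n_traced"] = len(particles)
    log["n_accepted"] = len(accepted)

    report = {"config": dataclasses.asdict(config), "counts": log}
    if accepted:
        summary = loc.precision_summary(accepted)
        report["precision"] = summary
        _, _, pooled = projgeom.pairwise_distance_histogram(
            [p.positions_nm for p in accepted])
        report["n_pairwise_distances"] = int(pooled.size)
        if model.n_labels == 2 and pooled.size >= 10:
            fit = projgeom.fit_projection_distance(pooled)
            report["distance_fit"] = {
                "d_nm": fit.d_nm, "sigma_nm": fit.sigma_nm,
                "d_ci_nm": list(fit.d_ci_nm)}
    if config.reconstruct and len(accepted) >= 5:
        from . import reconstruct3d as r3
        k = model.n_labels
        usable = [p for p in accepted if len(p.positions) == k]
        if len(usable) >= 5:
            rec = r3.reconstruct_class(
                [p.positions_nm for p in usable], rng,
                noise_sigma_nm=report.get("precision", {}).get(
                    "median_precision_nm"))
            nn = rec.nearest_neighbor_distances()
            report["reconstruction"] = {
                "n_particles": rec.n_particles,
                "median_nn_nm": float(np.median(nn)),
                "degenerate": rec.degenerate}
        else:
            warnings.warn("too few fully labeled particles to reconstruct")
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=float))
    return report
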