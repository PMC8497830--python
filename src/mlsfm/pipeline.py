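"""The end-to-end multi-scale acquisition pipeline on a synthetic brain.

Stages: phantom generation -> low-zoom overview and sample-boundary
detection -> detection pass mosaic (zoom 1.6x) -> tile triage -> high-zoom
rescan (6.3x) of flagged tiles only -> sectioning schedule -> detection
metrics and cost accounting.  Everything is deterministic given the single
run seed, which is expanded into named substreams per stage and per tile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import acquisition as acq
from . import triage as tri
from .io import RunManifest, config_hash, write_tile_stack
from .optics import DetectionPath, ObjectiveSpec, SheetModel
from .phantom import PhantomConfig, PhantomVolume, generate_neurons, rasterize
from .seeding import substream_rng

__all__ = ["PipelineConfig", "PipelineResult", "default_detection_path", "run_pipeline"]


def default_detection_path(zoom: float = 1.0, sensor_px: int = 96) -> DetectionPath:
    """The macroscope detection chain: 2x / NA 0.5 objective, zoom body,
    6.5 um camera pitch.  Small sensor crops keep demo runs desk-sized."""
    return DetectionPath(
        objective=ObjectiveSpec(
            name="MVPLAPO-2X", numerical_aperture=0.5, magnification=2.0,
            working_distance_mm=20.0, immersion_index=1.0,
        ),
        zoom=zoom,
        camera_pixel_pitch_um=6.5,
        sensor_shape_px=(sensor_px, sensor_px),
        emission_wavelength_um=0.52,
    )


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = PhantomConfig()
    acquisition: acq.AcquisitionConfig = acq.AcquisitionConfig()
    triage: tri.TriageConfig = tri.TriageConfig()
    sheet: SheetModel = SheetModel()
    sensor_px: int = 96
    rescan_policy: str = "any_signal"
    restrict_to_boundary: bool = True
    boundary_margin_px: int = 10
    mode: str = "tiled"
    simulate_rescan: bool = True


@dataclass
class PipelineResult:
    manifest: RunManifest
    phantom: PhantomVolume
    decisions: list[tri.TriageDecision]
    metrics: tri.DetectionMetrics
    truth_occupancy: dict[str, bool]
    bright_occupancy: dict[str, bool]
    tile_snr: dict[str, float]
    pass1_plans: list[acq.TilePlan]
    pass2_plans: list[acq.TilePlan]
    pass2_full_plans: list[acq.TilePlan]
    costs: dict[str, acq.CostEstimate]
    sections: acq.SectionSchedule


def _tile_occupancy(mask, plan: acq.TilePlan, voxel_size) -> bool:
    """True if any truth voxel lies in the tile's XY footprint."""
    vz, vy, vx = voxel_size
    ny, nx = mask.shape[1], mask.shape[2]
    y0 = max(0, int(plan.y_um / vy))
    y1 = min(ny, int(-(-(plan.y_um + plan.fov_y_um) // vy)))
    x0 = max(0, int(plan.x_um / vx))
    x1 = min(nx, int(-(-(plan.x_um + plan.fov_x_um) // vx)))
    if y1 <= y0 or x1 <= x0:
        return False
    return bool(mask[:, y0:y1, x0:x1].any())


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    outdir=None,
) -> PipelineResult:
    """Execute the full multi-scale procedure; deterministic given ``seed``."""
    from pathlib import Path

    acfg = config.acquisition
    overview_pass, detect_pass, high_pass = acfg.zoom_schedule[:3]
    phantom_rng = substream_rng(seed, "phantom")
    trees = generate_neurons(config.phantom, rng=phantom_rng)
    phantom = rasterize(trees, config.phantom)
    ez, ey, ex = phantom.extent_um
    vz, vy, vx = phantom.voxel_size_um
    z_lo, z_hi = vz, max(vz, ez - 2.0 * vz)

    # ---- pass 0: overview at the lowest zoom, find the sample boundary
    det0 = default_detection_path(overview_pass.zoom, config.sensor_px)
    px0 = det0.pixel_size_um
    overview_plan = acq.TilePlan(
        tile_id="p0_overview", pass_index=0, x_um=0.0, y_um=0.0,
        fov_y_um=ey, fov_x_um=ex, z_min_um=z_lo, z_max_um=z_hi,
        z_step_um=max((z_hi - z_lo) / 2.0, vz), zoom=overview_pass.zoom,
    )
    overview = acq.simulate_stack(
        phantom, overview_plan, det0, config.sheet, mode=config.mode,
        config=acfg, rng=substream_rng(seed, "acquire/p0"),
    )
    box = acq.detect_sample_boundary(
        tri.mip_z(overview), margin_px=config.boundary_margin_px
    )
    if box is not None and config.restrict_to_boundary:
        bounds = (
            (box.row_min * px0, box.row_max * px0),
            (box.col_min * px0, box.col_max * px0),
        )
    else:
        bounds = ((0.0, ey), (0.0, ex))

    # ---- pass 1: detection mosaic
    det1 = default_detection_path(detect_pass.zoom, config.sensor_px)
    fov1 = det1.fov_um
    pass1_plans = acq.plan_mosaic(
        bounds, fov1, acfg.xy_overlap_fraction, zoom=detect_pass.zoom,
        z_range_um=(z_lo, z_hi), z_step_um=detect_pass.z_step_um, pass_index=1,
    )
    decisions = []
    tile_records = []
    for plan in pass1_plans:
        stack = acq.simulate_stack(
            phantom, plan, det1, config.sheet, mode=config.mode, config=acfg,
            rng=substream_rng(seed, f"acquire/{plan.tile_id}"),
        )
        decision = tri.triage_tile(stack, config.triage, tile_id=plan.tile_id)
        decisions.append(decision)
        if outdir is not None:
            write_tile_stack(Path(outdir) / f"{plan.tile_id}.tif", stack)
        tile_records.append(
            {
                "tile_id": plan.tile_id, "pass": 1,
                "origin_um": [plan.x_um, plan.y_um, plan.z_min_um],
                "zoom": plan.zoom, "n_z": plan.n_z,
            }
        )

    rescan_ids = tri.select_rescan_tiles(decisions, config.rescan_policy)
    truth_occ = {
        p.tile_id: _tile_occupancy(
            phantom.truth_masks["signal"], p, phantom.voxel_size_um
        )
        for p in pass1_plans
    }
    bright_occ = {
        p.tile_id: _tile_occupancy(
            phantom.truth_masks["bright"], p, phantom.voxel_size_um
        )
        for p in pass1_plans
    }
    tile_snr = {
        d.tile_id: s for d in decisions if (s := d.tile_snr()) is not None
    }
    metrics = tri.evaluate(rescan_ids, truth_occ, tile_snr)

    # ---- pass 2: high-magnification rescan of flagged tiles only
    det2 = default_detection_path(high_pass.zoom, config.sensor_px)
    fov2 = det2.fov_um

    def plan_pass2(parent: acq.TilePlan) -> list[acq.TilePlan]:
        sub = acq.plan_mosaic(
            ((parent.y_um, parent.y_um + parent.fov_y_um),
             (parent.x_um, parent.x_um + parent.fov_x_um)),
            fov2, acfg.xy_overlap_fraction, zoom=high_pass.zoom,
            z_range_um=(z_lo, z_hi), z_step_um=high_pass.z_step_um, pass_index=2,
        )
        return [
            replace(p, tile_id=f"{parent.tile_id}/{p.tile_id}") for p in sub
        ]

    pass2_plans = [p for t in pass1_plans if t.tile_id in set(rescan_ids)
                   for p in plan_pass2(t)]
    pass2_full_plans = [p for t in pass1_plans for p in plan_pass2(t)]
    if config.simulate_rescan:
        for plan in pass2_plans:
            stack = acq.simulate_stack(
                phantom, plan, det2, config.sheet, mode=config.mode, config=acfg,
                rng=substream_rng(seed, f"acquire/{plan.tile_id}"),
                allow_outside=True,
            )
            if outdir is not None:
                write_tile_stack(
                    Path(outdir) / f"{plan.tile_id.replace('/', '_')}.tif", stack
                )
            tile_records.append(
                {
                    "tile_id": plan.tile_id, "pass": 2,
                    "origin_um": [plan.x_um, plan.y_um, plan.z_min_um],
                    "zoom": plan.zoom, "n_z": plan.n_z,
                }
            )

    sections = acq.plan_sections(
        ez, ez, min(acfg.section_overlap_um, 0.5 * ez)
    )
    sensor = (config.sensor_px, config.sensor_px)
    costs = {
        "pass1": acq.cost_model(pass1_plans, acfg, sensor),
        "pass2": acq.cost_model(pass2_plans, acfg, sensor,
                                n_cuts=len(sections.cuts)),
        "pass2_full_coverage": acq.cost_model(pass2_full_plans, acfg, sensor),
    }

    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=int(seed),
        passes=[
            {"pass": 0, "zoom": overview_pass.zoom, "n_tiles": 1},
            {"pass": 1, "zoom": detect_pass.zoom, "n_tiles": len(pass1_plans)},
            {"pass": 2, "zoom": high_pass.zoom, "n_tiles": len(pass2_plans)},
        ],
        tiles=tile_records,
        metrics={
            "fp_rate": metrics.fp_rate,
            "fn_rate": metrics.fn_rate,
            "n_tiles_total": metrics.n_tiles_total,
            "n_tiles_rescanned": metrics.n_tiles_rescanned,
            "rescan_ids": sorted(rescan_ids),
        },
    )
    result = PipelineResult(
        manifest=manifest, phantom=phantom, decisions=decisions,
        metrics=metrics, truth_occupancy=truth_occ, bright_occupancy=bright_occ,
        tile_snr=tile_snr, pass1_plans=pass1_plans, pass2_plans=pass2_plans,
        pass2_full_plans=pass2_full_plans, costs=costs, sections=sections,
    )
    if outdir is not None:
        manifest.write(Path(outdir) / "manifest.json")
    return result
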