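"""End-to-end orchestration: volume -> delineation -> segmentation ->
thickness -> wall map -> indices, with every intermediate artifact written
out and a run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics as mt
from . import segmentation as seg
from . import thickness as th
from . import unwrap
from .phantom import CTParams, PhantomSpec, auto_delineation, simulate_ct, voxelize_phantom, gold_standard_map
from .volume import CTVolume

log = logging.getLogger("atriamap")

__all__ = ["PipelineConfig", "PipelineResult", "run_measurement", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of one run.  Exactly one of ``volume_path``
    (a CT scan on disk) or ``phantom`` (generate and simulate) is given."""

    volume_path: str | None = None
    delineation_path: str | None = None
    phantom: PhantomSpec | None = None
    ct_params: CTParams = field(default_factory=CTParams)
    lumen_threshold: float | None = None
    sobel_refine: bool = False
    r_max: float = 10.0
    reference_direction: tuple[float, float] = (1.0, 0.0)
    out_dir: str = "atriamap_out"
    rng_seed: int = 0
    log_level: str = "INFO"
    compare_gold: bool = True  # phantom mode: also build the gold map

    def validate(self) -> None:
        if (self.volume_path is None) == (self.phantom is None):
            raise ValueError("exactly one of volume input or phantom spec "
                             "must be supplied")
        for p in (self.volume_path, self.delineation_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    volume: CTVolume
    delineation: seg.Delineation
    chamber: seg.ChamberSegmentation
    wall: seg.WallSegmentation
    field: th.ThicknessField
    wall_map: unwrap.WallMap
    indices: mt.GeometricIndices
    gold_map: unwrap.WallMap | None = None
    comparison: mt.MapComparison | None = None
    manifest: dict = field(default_factory=dict)


def run_measurement(volume: CTVolume, config: seg.DelineationConfig,
                    lumen_threshold: float | None = None,
                    sobel_refine: bool = False, r_max: float = 10.0,
                    reference_direction=(1.0, 0.0)) -> PipelineResult:
    """The measurement path on an HU volume: Procedures 1-5 in sequence."""
    timings = {}
    t0 = time.perf_counter()
    delin = seg.delineate(volume, config)
    timings["delineate"] = time.perf_counter() - t0
    log.info("delineation: isocentre=%s clipped=%d voxels",
             delin.isocentre, int(delin.clipped.sum()))

    t0 = time.perf_counter()
    chamber = seg.segment_inner(volume, delin, lumen_threshold=lumen_threshold,
                                sobel_refine=sobel_refine)
    timings["segment_inner"] = time.perf_counter() - t0
    log.info("inner: threshold=%.1f HU, %d chamber voxels, %d boundary voxels",
             chamber.lumen_threshold, int(chamber.chamber_mask.sum()),
             len(chamber.inner_boundary))

    t0 = time.perf_counter()
    wall = seg.segment_outer(volume, chamber, delin, r_max=r_max)
    timings["segment_outer"] = time.perf_counter() - t0
    log.info("outer: Otsu=%.1f HU after %d iterations, %d wall voxels",
             wall.otsu_threshold, wall.n_iterations, int(wall.wall_mask.sum()))

    t0 = time.perf_counter()
    field_ = th.compute_thickness(chamber.inner_boundary, wall.outer_boundary,
                                  volume.shape, volume.spacing)
    timings["thickness"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    holes3d = seg.ostium_mask(config, volume.shape, volume.spacing,
                              volume.origin)
    wmap = unwrap.build_wall_map(chamber, field_, delin, volume.spacing,
                                 reference_direction=reference_direction,
                                 hole_mask=holes3d, origin=volume.origin)
    timings["unwrap"] = time.perf_counter() - t0

    indices = mt.compute_indices(chamber, wall, field_, wmap, delin)
    return PipelineResult(volume=volume, delineation=delin, chamber=chamber,
                          wall=wall, field=field_, wall_map=wmap,
                          indices=indices,
                          manifest={"timings_s": timings})


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute a full configured run and write all artifacts to
    ``config.out_dir``.  Reruns with identical config and seed are
    bit-identical."""
    from . import io as amio  # local import: io pulls optional heavy deps

    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.rng_seed, "stages": {}}

    if config.phantom is not None:
        spec = config.phantom
        params = CTParams(**{**config.ct_params.__dict__, "rng_seed": config.rng_seed})
        truth = voxelize_phantom(spec)
        volume = simulate_ct(truth, params)
        delin_config = auto_delineation(spec)
        amio.write_labels(out / "truth_labels.nii", truth)
        manifest["mode"] = "phantom"
        manifest["ct_params"] = params.__dict__
    else:
        volume = amio.read_volume(config.volume_path)
        if config.delineation_path is None:
            raise ValueError("a delineation config is required for CT input")
        delin_config = amio.read_delineation(config.delineation_path)
        truth = None
        spec = None
        manifest["mode"] = "ct"

    amio.write_volume(out / "volume.nii", volume)
    result = run_measurement(volume, delin_config,
                             lumen_threshold=config.lumen_threshold,
                             sobel_refine=config.sobel_refine,
                             r_max=config.r_max,
                             reference_direction=config.reference_direction)

    if config.phantom is not None and config.compare_gold:
        gold = gold_standard_map(truth, spec)
        result.gold_map = gold
        gold_indices = _gold_indices(truth, spec, gold)
        result.comparison = mt.compare_maps(result.wall_map, gold,
                                            indices_measurement=result.indices,
                                            indices_gold=gold_indices)
        amio.write_map(out / "gold_map", gold)
        amio.write_comparison(out / "comparison", result.comparison)

    amio.write_masks(out / "segmentation.nii", result)
    amio.write_field(out / "thickness.csv", result.field)
    amio.write_map(out / "wall_map", result.wall_map)
    amio.write_indices(out / "indices.csv", result.indices)
    amio.render_map(out / "wall_map.png", result.wall_map)

    manifest["stages"].update(result.manifest.get("timings_s", {}))
    manifest["indices"] = result.indices.as_dict()
    import atriamap
    manifest["version"] = getattr(atriamap, "__version__", "unknown")
    result.manifest = manifest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def _gold_indices(truth, spec, gold_map) -> mt.GeometricIndices:
    """Geometric index panel of the truth-labelled phantom (gold standard)."""
    from .phantom import LABEL_LUMEN, LABEL_WALL

    config = auto_delineation(spec)
    clipped = seg.rasterize_clip(config, truth.shape, truth.spacing, truth.origin)
    chamber_mask = (truth.labels == LABEL_LUMEN) & ~clipped
    wall_mask = (truth.labels == LABEL_WALL) & ~clipped
    n_rows = gold_map.grid.shape[0]
    comps = mt.label_pv_holes(gold_map, _DelinShim(config))
    pv_areas = {c.name: c.area for c in comps} if len(comps) == 4 else {}
    return mt.GeometricIndices(
        chamber_volume=th.chamber_volume(chamber_mask, truth.spacing),
        wall_volume=th.wall_volume(wall_mask, truth.spacing),
        height=(int(gold_map.row_slices[-1]) - int(gold_map.row_slices[0]) + 1)
        * gold_map.row_spacing,
        ccl=sum(gold_map.arc_weights[n_rows // 2][gold_map.mapped_mask()[n_rows // 2]]),
        bcl=sum(gold_map.arc_weights[n_rows - 1][gold_map.mapped_mask()[n_rows - 1]]),
        pv_areas=pv_areas,
        mean_thickness=mt.weighted_mean_thickness(gold_map),
        heterogeneity=mt.heterogeneity(gold_map))


class _DelinShim:
    def __init__(self, config):
        self.config = config
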