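"""End-to-end pipeline orchestration and group summaries.

``run_pipeline`` chains denoise → segment → fabric/align → whole-bone
mask → trabecular mask → cortical mask → sphere fit (+ trabecular
re-fit) → partition → morphometry → cyst screen, writing the region CSV,
the cyst report and a JSON run log (config, seeds, versions) so a run
can be reproduced byte-for-byte.

Group comparison is deliberately descriptive only (median, IQR,
min–max per region across specimens); no hypothesis tests are computed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConsistencyError, FemheadError
from .head_geometry import fit_sphere, partition, refit_on_trabecular
from .lesion_screen import cyst_summary, flag_cysts
from .masking import (SliceROISet, cortical_mask, interpolate_trabecular_mask,
                      rois_from_mask, whole_bone_mask)
from .morphometry import local_thickness, plate_metrics, summarize_regions
from .phantom import PhantomSpec, generate
from .preprocess import (align, apply_transform, central_roi, denoise,
                         estimate_fabric, segment)
from .volume_io import BinaryVolume, ScalarVolume, read_volume, write_labelmap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_groups"]


@dataclass
class RunConfig:
    """Every tunable pipeline parameter, with the standard defaults."""

    gaussian_support: int = 3
    gaussian_sigma: float = 1.2
    threshold_gsv: float = 39300.0
    closing_radius: float = 40.0
    shrinkwrap_bridge: float = 30.0
    roi_spacing: int = 25
    cortical_max_depth_slices: int = 257
    elevation_split: float = float(np.pi / 4)
    azimuth_width: float = float(np.pi / 4)
    cyst_threshold_um: float = 585.0
    low_bvtv_cutoff: float = 10.0
    fabric_n_directions: int = 128
    fabric_seed: int = 0
    align_to_mtd: bool = True
    osteophyte_mode: bool = True  # re-fit the sphere on the trabecular mask
    mirror_x: bool = False  # left femur: mirror the medio-lateral axis
    write_intermediates: bool = False

    def validate(self) -> None:
        for name in ("gaussian_sigma", "threshold_gsv", "closing_radius",
                     "cyst_threshold_um"):
            if getattr(self, name) <= 0:
                raise FemheadError(f"config value {name} must be positive")
        for name in ("elevation_split", "azimuth_width"):
            if not 0 < getattr(self, name) <= np.pi / 2:
                raise FemheadError(f"config angle {name} must be in (0, pi/2]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PipelineResult:
    regions: pd.DataFrame
    cysts: pd.DataFrame
    plate: pd.DataFrame | None
    sphere_whole: object
    sphere_trab: object
    transform: object | None
    labelmap: object
    log: dict


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            logger.info("stage: %s", self.n)
            return self

        def __exit__(self, et, ev, tb):
            if ev is not None and isinstance(ev, FemheadError):
                ev.args = (f"[stage {self.n}] {ev.args[0]}",) + ev.args[1:]
            return False

    return _Ctx(name)


def run_pipeline(
    source: ScalarVolume | PhantomSpec | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    rois: SliceROISet | None = None,
    trabecular_reference: BinaryVolume | None = None,
    fovea_direction=None,
    voxel_size_um: float | None = None,
) -> PipelineResult:
    """Run the full morphometry pipeline on a volume, file or phantom spec.

    The trabecular mask comes from ``rois`` (manual contours, the
    standard route) or from ``trabecular_reference`` (a mask volume from
    which contours are extracted every ``roi_spacing`` slices in the
    aligned frame, used with phantoms).  With neither, the whole-bone
    mask is analysed as trabecular and cortical metrics are reported
    missing.
    """
    config = config or RunConfig()
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "version": __version__,
                 "numpy": np.__version__, "stages": []}

    if isinstance(source, PhantomSpec):
        with _stage("phantom"):
            vol, _truth = generate(source)
            log["source"] = {"kind": "phantom", "seed": source.seed}
    elif isinstance(source, ScalarVolume):
        vol = source
        log["source"] = {"kind": "in-memory", "shape": list(vol.shape)}
    else:
        with _stage("read"):
            vol = read_volume(source, voxel_size_um=voxel_size_um)
            log["source"] = {"kind": "file", "path": str(source)}
    vs = vol.voxel_size
    log["voxel_size_um"] = vs

    with _stage("denoise"):
        den = denoise(vol, support=config.gaussian_support, sigma=config.gaussian_sigma)
    with _stage("segment"):
        seg = segment(den, threshold_gsv=config.threshold_gsv)

    transform = None
    if config.align_to_mtd:
        with _stage("align"):
            roi0 = central_roi(seg)
            fabric0 = estimate_fabric(
                seg, roi=roi0, n_directions=config.fabric_n_directions,
                seed=config.fabric_seed,
            )
            # grid angular resolution: ~1 voxel of motion at the head radius
            idx = np.argwhere(seg.data)
            r_extent = float(np.sqrt(((idx - idx.mean(axis=0)) ** 2).sum(axis=1)).max())
            skip_below = np.arctan(1.0 / max(r_extent, 1.0))
            raw_aligned, transform = align(
                vol, fabric0, fovea_direction=fovea_direction,
                skip_below_rad=skip_below,
            )
            # the paper's order: reposition the reconstruction, then filter
            if not np.allclose(transform.rotation, np.eye(3)):
                den = denoise(raw_aligned, support=config.gaussian_support,
                              sigma=config.gaussian_sigma)
                seg = segment(den, threshold_gsv=config.threshold_gsv)
            dev = np.degrees(np.arccos(np.clip(abs(float(fabric0.mtd[2])), 0, 1)))
            log["mtd_deviation_deg_before_align"] = dev

    with _stage("whole_bone_mask"):
        whole = whole_bone_mask(
            seg, closing_radius=config.closing_radius,
            bridge_gap=config.shrinkwrap_bridge,
        )

    with _stage("trabecular_mask"):
        if rois is None and trabecular_reference is not None:
            ref = trabecular_reference
            if transform is not None:
                ref = apply_transform(ref, transform, order=0)
            rois = rois_from_mask(ref, spacing=config.roi_spacing)
        if rois is not None:
            trab = interpolate_trabecular_mask(rois, whole.shape)
            trab = BinaryVolume(trab.data & whole.data, vs)
            cortical_available = True
        else:
            logger.warning(
                "no trabecular contours supplied; analysing the whole bone as "
                "trabecular and skipping cortical metrics"
            )
            trab = whole
            cortical_available = False

    cort = None
    if cortical_available:
        with _stage("cortical_mask"):
            cort = cortical_mask(
                whole, trab, max_depth_slices=config.cortical_max_depth_slices
            )

    with _stage("sphere_fit"):
        sphere_whole = fit_sphere(whole, exclude_below_estimate=True)
        sphere = sphere_whole
        if config.osteophyte_mode and cortical_available:
            sphere = refit_on_trabecular(trab, exclude_below_estimate=True)
        log["sphere_center_um"] = [float(x) for x in sphere.center]
        log["sphere_radius_um"] = float(sphere.radius)

    with _stage("partition"):
        labelmap = partition(
            trab, sphere, elevation_split=config.elevation_split,
            azimuth_width=config.azimuth_width, mirror_x=config.mirror_x,
        )

    with _stage("morphometry"):
        fabric = estimate_fabric(
            seg, roi=trab, n_directions=config.fabric_n_directions,
            seed=config.fabric_seed,
        )
        th_bone = local_thickness(
            BinaryVolume(seg.data & trab.data, vs), phase="bone"
        )
        th_bg = local_thickness(seg, phase="background", voi=trab)
        regions = summarize_regions(seg, labelmap, th_bone, th_bg, fabric=fabric)
        plate = None
        if cort is not None:
            if cort.count() == 0:
                logger.warning("cortical mask empty; plate metrics missing")
            plate = plate_metrics(cort, seg, labelmap, mirror_x=config.mirror_x)

    with _stage("cyst_screen"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cysts = flag_cysts(
                regions, threshold_um=config.cyst_threshold_um,
                low_bvtv_cutoff=config.low_bvtv_cutoff,
            )
        regions = regions.merge(
            cysts[["name", "flagged", "low_bvtv_note"]].rename(
                columns={"flagged": "cyst_flag"}),
            on="name", how="left",
        )

    if out is not None:
        regions.to_csv(out / "regions.csv", index=False, float_format="%.6g")
        cysts.to_csv(out / "cysts.csv", index=False, float_format="%.6g")
        if plate is not None:
            plate.to_csv(out / "plate.csv", index=False, float_format="%.6g")
        (out / "cyst_summary.json").write_text(json.dumps(cyst_summary(cysts), indent=2))
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        if config.write_intermediates:
            from .volume_io import write_volume

            write_volume(whole, out / "whole_mask.mha")
            write_volume(trab, out / "trabecular_mask.mha")
            if cort is not None:
                write_volume(cort, out / "cortical_mask.mha")
            write_labelmap(labelmap, out / "labels.mha")

    return PipelineResult(
        regions=regions, cysts=cysts, plate=plate, sphere_whole=sphere_whole,
        sphere_trab=sphere, transform=transform, labelmap=labelmap, log=log,
    )


_METRICS = ["BV_TV", "Tb_Th_mean", "Tb_Th_sd", "Tb_Sp_mean", "Tb_Sp_sd",
            "Tb_N", "Conn_D", "DA"]


def compare_groups(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Descriptive per-region summary across specimens.

    Returns median, IQR (q75 − q25) and min–max of each metric per
    region name.  No hypothesis tests: with small samples only trends
    are reported.
    """
    if not tables:
        raise ConsistencyError("need at least one region table")
    names = set(tables[0]["name"])
    for t in tables[1:]:
        if set(t["name"]) != names:
            raise ConsistencyError("specimens have mismatched region sets")
    stacked = pd.concat(tables, keys=range(len(tables)), names=["specimen"])
    rows = []
    for name, grp in stacked.groupby("name", sort=False):
        row = {"name": name, "n_specimens": len(grp)}
        for m in _METRICS:
            if m not in grp:
                continue
            v = grp[m].astype(float)
            v = v[np.isfinite(v)]
            if v.empty:
                continue
            row[f"{m}_median"] = float(v.median())
            row[f"{m}_iqr"] = float(v.quantile(0.75) - v.quantile(0.25))
            row[f"{m}_min"] = float(v.min())
            row[f"{m}_max"] = float(v.max())
        rows.append(row)
    return pd.DataFrame(rows)
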