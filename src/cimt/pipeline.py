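"""End-to-end orchestration of the six-stage measurement pipeline.

Stages: (1) template-matched ROI extraction, (2) bilateral speckle
filtering, (3) threshold-based initial LII estimation, (4) edge-based
initial MAI estimation, (5) dynamic-programming boundary refinement,
(6) IMT measurement with the 0.2-1.6 mm validity gate.

Every stage is deterministic, so identical inputs and configuration
produce identical results.  In batch mode a stage failure marks the
image as failed (with the stage named in the failure reason) instead of
aborting the run; agreement statistics are computed over the validly
measured images only.
"""

from __future__ import annotations

import glob
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boundary_init, dp_refine, measurement, roi
from .boundary_init import Boundary, EdgeMap, HistogramAnalysis
from .denoise import BilateralParams, bilateral_filter
from .errors import CimtError, InitializationFailure, RoiFailure
from .image_io import (
    DEFAULT_PIXEL_DENSITY,
    CropWindow,
    GrayImage,
    crop_image,
    load_image,
    write_results_table,
)
from .measurement import AgreementStats, IMTResult
from .roi import MatchSet, ROIBox, Template
from .synthetic import CohortSample

log = logging.getLogger("cimt.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the pipeline.

    The defaults reproduce the reference operating point:
    ROI half-height d=20 px, intensity threshold T1=0.1, closing element
    size r=15 px, curvature weight lambda=-0.2.
    """

    roi_half_height: int = 20
    lii_threshold: float = 0.1
    adaptive_threshold: bool = False
    closing_size: int = 15
    curvature_weight: float = -0.2
    band_halfwidth: int = 1
    max_passes: int = 20
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    imt_range_mm: tuple[float, float] = boundary_init.DEFAULT_IMT_RANGE_MM
    valid_range_mm: tuple[float, float] = measurement.DEFAULT_VALID_RANGE_MM
    n_match_lines: int = 7
    agreement_mm: float = 2.0
    min_agree: int = 4
    edge_kernel_size: int = 10
    edge_sigma: float = 1.0
    crop: CropWindow | None = None
    pixel_density: float = DEFAULT_PIXEL_DENSITY

    @property
    def dp(self) -> dp_refine.DPConfig:
        return dp_refine.DPConfig(
            curvature_weight=self.curvature_weight,
            band_halfwidth=self.band_halfwidth,
            max_passes=self.max_passes,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "bilateral" in data:
            data["bilateral"] = BilateralParams(**data["bilateral"])
        if data.get("crop") is not None:
            data["crop"] = CropWindow(**data["crop"])
        for key in ("imt_range_mm", "valid_range_mm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "roi_half_height": self.roi_half_height,
            "lii_threshold": self.lii_threshold,
            "adaptive_threshold": self.adaptive_threshold,
            "closing_size": self.closing_size,
            "curvature_weight": self.curvature_weight,
            "band_halfwidth": self.band_halfwidth,
            "max_passes": self.max_passes,
            "bilateral": {
                "sigma_spatial": self.bilateral.sigma_spatial,
                "sigma_range": self.bilateral.sigma_range,
                "window_radius": self.bilateral.window_radius,
            },
            "imt_range_mm": list(self.imt_range_mm),
            "valid_range_mm": list(self.valid_range_mm),
            "n_match_lines": self.n_match_lines,
            "agreement_mm": self.agreement_mm,
            "min_agree": self.min_agree,
            "edge_kernel_size": self.edge_kernel_size,
            "edge_sigma": self.edge_sigma,
            "crop": None
            if self.crop is None
            else {
                "row_start": self.crop.row_start,
                "row_end": self.crop.row_end,
                "col_start": self.crop.col_start,
                "col_end": self.crop.col_end,
            },
            "pixel_density": self.pixel_density,
        }
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class PipelineArtifacts:
    """Per-stage intermediates, retrievable for debugging/overlays."""

    cropped: GrayImage | None = None
    matches: MatchSet | None = None
    roi_image: GrayImage | None = None
    roi_box: ROIBox | None = None
    filtered: GrayImage | None = None
    histogram: HistogramAnalysis | None = None
    threshold_used: float | None = None
    lii_estimated: Boundary | None = None
    edge_map: EdgeMap | None = None
    mai_estimated: Boundary | None = None
    mai_displacement_px: int | None = None
    lii_refined: Boundary | None = None
    mai_refined: Boundary | None = None
    lii_energies: list[float] | None = None
    mai_energies: list[float] | None = None


def run_pipeline(
    img: GrayImage, tmpl: Template, cfg: PipelineConfig = PipelineConfig()
) -> tuple[IMTResult, PipelineArtifacts]:
    """Measure one image; stage failures yield a failed result naming the
    stage, never an exception (callers wanting exceptions can inspect
    ``failure_reason``)."""
    art = PipelineArtifacts()
    stage = "crop"
    try:
        work = crop_image(img, cfg.crop) if cfg.crop is not None else img
        art.cropped = work

        stage = "roi-extraction"
        matches = roi.find_matches(work, tmpl, n_lines=cfg.n_match_lines)
        matches = roi.reject_outliers(
            matches, work, agreement_mm=cfg.agreement_mm, min_agree=cfg.min_agree
        )
        art.matches = matches
        roi_img, box = roi.extract_roi(work, matches, d=cfg.roi_half_height)
        art.roi_image, art.roi_box = roi_img, box
        log.info("roi-extraction: box=%s", box)

        stage = "bilateral-filter"
        filtered = bilateral_filter(roi_img, cfg.bilateral)
        art.filtered = filtered

        stage = "lii-estimation"
        hist = boundary_init.analyze_histogram(filtered)
        art.histogram = hist
        threshold = cfg.lii_threshold
        if cfg.adaptive_threshold and hist.t1 is not None and not hist.ambiguous:
            threshold = hist.t1
        art.threshold_used = threshold
        log.info("lii-estimation: threshold=%.4f ambiguous=%s", threshold, hist.ambiguous)
        lii_est = boundary_init.estimate_lii(filtered, threshold, cfg.closing_size)
        art.lii_estimated = lii_est

        stage = "mai-estimation"
        emap = boundary_init.edge_map(filtered, cfg.edge_kernel_size, cfg.edge_sigma)
        art.edge_map = emap
        mai_est, delta = boundary_init.estimate_mai(lii_est, emap, filtered, cfg.imt_range_mm)
        art.mai_estimated, art.mai_displacement_px = mai_est, delta
        log.info("mai-estimation: displacement=%d px", delta)

        stage = "dp-refinement"
        lii_ref, lii_e = dp_refine.refine(lii_est, emap, cfg.dp)
        mai_ref, mai_e = dp_refine.refine(mai_est, emap, cfg.dp)
        art.lii_refined, art.mai_refined = lii_ref, mai_ref
        art.lii_energies, art.mai_energies = lii_e, mai_e
        log.info(
            "dp-refinement: lii passes=%d energy=%.4f | mai passes=%d energy=%.4f",
            len(lii_e), lii_e[-1], len(mai_e), mai_e[-1],
        )

        stage = "measurement"
        result = measurement.compute_imt(
            lii_ref, mai_ref, img.pixel_density, cfg.valid_range_mm
        )
        if not result.valid:
            result = IMTResult(
                result.per_column_mm, result.mean_mm, result.min_mm, result.max_mm,
                False, f"measurement: {result.failure_reason}",
            )
        return result, art
    except (RoiFailure, InitializationFailure, CimtError) as exc:
        log.info("stage %s failed: %s", stage, exc)
        return IMTResult.failed(f"{stage}: {exc}"), art


def run_cohort(
    samples: list[CohortSample], tmpl: Template, cfg: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, AgreementStats | None]:
    """Measure an in-memory phantom cohort and compare with its ground
    truth.  Failed images are reported in the frame and excluded from the
    agreement statistics."""
    records = []
    for i, s in enumerate(samples):
        result, _ = run_pipeline(s.image, tmpl, cfg)
        records.append(
            {
                "path": f"phantom_{i:04d}",
                "status": "ok" if result.valid else "failed",
                "mean_imt_mm": result.mean_mm,
                "min_mm": result.min_mm,
                "max_mm": result.max_mm,
                "failure_reason": result.failure_reason,
                "gt_imt_mm": s.gt_imt_mm,
            }
        )
    frame = pd.DataFrame.from_records(records)
    ok = frame[frame["status"] == "ok"]
    stats_ = None
    if len(ok) >= 2:
        stats_ = measurement.bland_altman(
            ok["mean_imt_mm"].to_numpy(), ok["gt_imt_mm"].to_numpy()
        )
    return frame, stats_


def run_batch(
    image_dir: str | Path,
    tmpl: Template,
    cfg: PipelineConfig = PipelineConfig(),
    out_csv: str | Path | None = None,
    gt_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, AgreementStats | None]:
    """Measure every PNG/TIFF image in a directory.

    With a ground-truth CSV (columns ``path, gt_imt_mm``, paths relative
    to the directory) agreement statistics are computed over the validly
    measured images.
    """
    image_dir = Path(image_dir)
    paths = sorted(
        p for pattern in ("*.png", "*.tif", "*.tiff") for p in glob.glob(str(image_dir / pattern))
    )
    if not paths:
        raise CimtError(f"no PNG/TIFF images found in {image_dir}")
    gt_map: dict[str, float] = {}
    if gt_csv is not None:
        gt_frame = pd.read_csv(gt_csv)
        gt_map = dict(zip(gt_frame["path"].astype(str), gt_frame["gt_imt_mm"].astype(float)))
    records = []
    for path in paths:
        name = Path(path).name
        img = load_image(path, pixel_density=cfg.pixel_density)
        result, _ = run_pipeline(img, tmpl, cfg)
        rec = {
            "path": name,
            "status": "ok" if result.valid else "failed",
            "mean_imt_mm": result.mean_mm,
            "min_mm": result.min_mm,
            "max_mm": result.max_mm,
            "failure_reason": result.failure_reason,
        }
        if name in gt_map:
            rec["gt_imt_mm"] = gt_map[name]
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    if out_csv is not None:
        write_results_table(records, out_csv)
    stats_ = None
    if gt_map:
        ok = frame[(frame["status"] == "ok") & frame["gt_imt_mm"].notna()]
        if len(ok) >= 2:
            stats_ = measurement.bland_altman(
                ok["mean_imt_mm"].to_numpy(), ok["gt_imt_mm"].to_numpy()
            )
    return frame, stats_
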