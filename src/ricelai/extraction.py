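"""Pixel/plot quality filters and plot-level aggregation.

A pixel is "bad" when its DN exceeds 250 in *every* band (water specular
saturation); a plot is invalid when its observation ROI holds more than 100
bad pixels. Valid plots are summarised by the per-band mean reflectance over
unmasked ROI pixels, the mean canopy height H = DSM - DSM_soil, and the
destructively measured LAI = LA / n * density (n = 3 bundles, density =
22.5 bundles/m2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, apply_calibration
from .exceptions import BoundsError, EmptyROIError
from .synthetic import (
    CampaignScene,
    CultivarParams,
    PlotROI,
    SamplingRecord,
)

logger = logging.getLogger(__name__)

BAD_PIXEL_DN_THRESHOLD = 250
MAX_BAD_PIXELS_PER_PLOT = 100


@dataclass(frozen=True)
class BadPixelMask:
    """Boolean grid marking saturated pixels (True = bad)."""

    mask: np.ndarray

    def count_in(self, roi: PlotROI) -> int:
        self._check_bounds(roi)
        rs, cs = roi.slices()
        return int(np.count_nonzero(self.mask[rs, cs]))

    def _check_bounds(self, roi: PlotROI) -> None:
        h, w = self.mask.shape
        if not (0 <= roi.row0 <= roi.row1 <= h and 0 <= roi.col0 <= roi.col1 <= w):
            raise BoundsError(
                f"ROI {roi.plot_id} [{roi.row0}:{roi.row1}, "
                f"{roi.col0}:{roi.col1}] outside grid {self.mask.shape}"
            )


@dataclass(frozen=True)
class PlotObservation:
    """One plot x date record feeding the LAI models."""

    plot_id: str
    cultivar_id: str
    dat: int
    reflectance: np.ndarray  # (12,)
    height: float            # m
    lai: float               # measured, unitless
    stage: str               # "pre-heading" | "post-heading"
    valid: bool


def mask_bad_pixels(
    dn_raster: np.ndarray, threshold: int = BAD_PIXEL_DN_THRESHOLD
) -> BadPixelMask:
    """Mark pixels whose DN strictly exceeds ``threshold`` in every band."""
    dn = np.asarray(dn_raster)
    if dn.ndim != 3:
        raise ValueError(f"expected (bands, rows, cols) raster, got {dn.shape}")
    if not np.issubdtype(dn.dtype, np.integer):
        raise ValueError("bad-pixel masking operates on the integer DN raster")
    return BadPixelMask(mask=np.all(dn > threshold, axis=0))


def assess_plot_validity(
    roi: PlotROI,
    mask: BadPixelMask,
    max_bad: int = MAX_BAD_PIXELS_PER_PLOT,
) -> bool:
    """A plot is valid unless its ROI holds strictly more than ``max_bad``
    bad pixels."""
    return mask.count_in(roi) <= max_bad


def plot_mean_reflectance(
    reflectance_raster: np.ndarray,
    roi: PlotROI,
    mask: BadPixelMask | None = None,
) -> np.ndarray:
    """Per-band mean reflectance over ROI pixels, excluding masked pixels."""
    refl = np.asarray(reflectance_raster, dtype=float)
    if refl.ndim != 3:
        raise ValueError(f"expected (bands, rows, cols) raster, got {refl.shape}")
    rs, cs = roi.slices()
    block = refl[:, rs, cs]
    if mask is not None:
        mask._check_bounds(roi)
        keep = ~mask.mask[rs, cs]
        if not keep.any():
            raise EmptyROIError(
                f"all pixels of ROI {roi.plot_id} are masked"
            )
        return block[:, keep].mean(axis=1)
    if block.shape[1] * block.shape[2] == 0:
        raise EmptyROIError(f"ROI {roi.plot_id} is empty")
    return block.mean(axis=(1, 2))


def plot_canopy_height(
    dsm: np.ndarray, dsm_soil: np.ndarray, roi: PlotROI
) -> float:
    """Mean over the ROI of (DSM - bare-soil DSM); negative per-pixel
    differences are clamped to 0 with a logged count."""
    dsm = np.asarray(dsm, dtype=float)
    dsm_soil = np.asarray(dsm_soil, dtype=float)
    if dsm.shape != dsm_soil.shape:
        raise ValueError(
            f"DSM grids are misaligned: {dsm.shape} vs {dsm_soil.shape}"
        )
    h, w = dsm.shape
    if not (0 <= roi.row0 <= roi.row1 <= h and 0 <= roi.col0 <= roi.col1 <= w):
        raise BoundsError(f"ROI {roi.plot_id} outside DSM grid {dsm.shape}")
    rs, cs = roi.slices()
    diff = dsm[rs, cs] - dsm_soil[rs, cs]
    n_neg = int(np.count_nonzero(diff < 0))
    if n_neg:
        logger.info("ROI %s: clamped %d negative height pixels", roi.plot_id,
                    n_neg)
        diff = np.clip(diff, 0.0, None)
    return float(diff.mean())


def compute_measured_lai(record: SamplingRecord) -> float:
    """Destructive LAI = (sum of bundle leaf areas) / n_bundles * density."""
    if record.n_bundles < 1:
        raise ValueError(f"n_bundles must be >= 1, got {record.n_bundles}")
    if record.plant_density <= 0:
        raise ValueError(
            f"plant density must be positive, got {record.plant_density}"
        )
    if any(la < 0 for la in record.leaf_areas):
        raise ValueError("leaf areas must be non-negative")
    return float(sum(record.leaf_areas) / record.n_bundles
                 * record.plant_density)


def assign_stage(dat: int, heading_dat: int) -> str:
    """Pre-heading strictly before the heading date; the heading date itself
    opens the post-heading stages (heading belongs to the reproductive
    phase)."""
    return "pre-heading" if dat < heading_dat else "post-heading"


def extract_observations(
    scene: CampaignScene,
    calibration: CalibrationModel,
    cultivars: list[CultivarParams],
    sampling: list[SamplingRecord],
    max_bad: int = MAX_BAD_PIXELS_PER_PLOT,
    bad_threshold: int = BAD_PIXEL_DN_THRESHOLD,
) -> list[PlotObservation]:
    """Run the full per-scene extraction: mask, validity, means, H, LAI."""
    mask = mask_bad_pixels(scene.dn, threshold=bad_threshold)
    refl = apply_calibration(scene.dn, calibration)
    cv_by_plot = {
        row.plot_id: row for row in scene.truth.itertuples()
    }
    cultivar_by_id = {c.cultivar_id: c for c in cultivars}
    lai_by_plot = {
        rec.plot_id: compute_measured_lai(rec)
        for rec in sampling if rec.dat == scene.dat
    }
    obs = []
    n_invalid = 0
    for roi in scene.plot_rois:
        valid = assess_plot_validity(roi, mask, max_bad=max_bad)
        truth_row = cv_by_plot[roi.plot_id]
        cultivar = cultivar_by_id[truth_row.cultivar_id]
        stage = assign_stage(scene.dat, cultivar.heading_dat)
        if valid:
            mean_refl = plot_mean_reflectance(refl, roi, mask)
            height = plot_canopy_height(scene.dsm, scene.dsm_soil, roi)
        else:
            n_invalid += 1
            mean_refl = np.full(calibration.n_bands, np.nan)
            height = float("nan")
        obs.append(PlotObservation(
            plot_id=roi.plot_id, cultivar_id=cultivar.cultivar_id,
            dat=scene.dat, reflectance=mean_refl, height=height,
            lai=lai_by_plot.get(roi.plot_id, float("nan")),
            stage=stage, valid=valid,
        ))
    if n_invalid:
        logger.info("dat %d: %d of %d plots invalid (> %d bad pixels)",
                    scene.dat, n_invalid, len(scene.plot_rois), max_bad)
    return obs


def observation_table(observations: list[PlotObservation]) -> pd.DataFrame:
    """Flatten observations to a tidy table (one band column per wavelength)."""
    from .indices import WAVELENGTHS_NM

    rows = []
    for o in observations:
        row = dict(plot_id=o.plot_id, cultivar_id=o.cultivar_id, dat=o.dat,
                   height=o.height, lai=o.lai, stage=o.stage, valid=o.valid)
        for wl, r in zip(WAVELENGTHS_NM, o.reflectance):
            row[f"r{wl}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
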