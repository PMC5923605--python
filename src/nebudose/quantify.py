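"""Micrograph quantification: calibrate → threshold → area → dose.

The pipeline mirrors how deposition micrographs are quantified in practice:

1. derive the area of one pixel from the known physical scan dimensions and
   the pixel grid (:func:`calibrate`);
2. mark a pixel as particle when its intensity is strictly greater than a
   threshold — fixed, or chosen automatically by between-class-variance
   (Otsu) maximization (:func:`segment`);
3. multiply the particle pixel count by the pixel area to get the total
   particle-occupied area, convert it to an areal dose under the
   sphere/monolayer model, and express it against the nominal dose as a
   deposition efficiency (:func:`estimate_dose`);
4. optionally summarize aggregation by connected components
   (:func:`aggregate_stats`).

The imaged field is taken as representative of the whole insert: the dose
measured on one field is reported as the insert-level dose.  Averaging over
several fields per condition is done one level up (see
:mod:`nebudose.pipeline`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .dosimetry import (
    DoseEstimate,
    ExposureSpec,
    ParticleSpec,
    area_to_dose,
    nominal_dose,
)
from .image import ImageCalibration, SEMImage
from . import units

__all__ = [
    "SegmentationResult",
    "AggregateStats",
    "calibrate",
    "segment",
    "dose_from_segmentation",
    "estimate_dose",
    "aggregate_stats",
]


@dataclass(frozen=True)
class SegmentationResult:
    """Binary particle mask plus the threshold it came from.

    total_np_area_um2 = np_pixel_count × pixel area, exactly.
    """

    mask: np.ndarray
    threshold_used: float
    np_pixel_count: int
    total_np_area_um2: float
    calibration: ImageCalibration


@dataclass(frozen=True)
class AggregateStats:
    """Connected-component summary of a particle mask.

    ``aggregate_area_fraction`` is the fraction of particle-occupied area
    sitting in components larger than a single-particle cutoff (twice the
    projected area of one primary particle) — 0 for perfectly dispersed
    fields, approaching 1 when most material is aggregated.
    """

    n_components: int
    component_areas_um2: np.ndarray
    largest_component_area_um2: float
    aggregate_area_fraction: float


def calibrate(
    scan_width_nm: float, scan_height_nm: float, pixels_x: int, pixels_y: int
) -> ImageCalibration:
    """Build an ImageCalibration; pixel area is the product of the per-axis
    pitches (scan_width/pixels_x) × (scan_height/pixels_y)."""
    return ImageCalibration(
        scan_width_nm=scan_width_nm,
        scan_height_nm=scan_height_nm,
        pixels_x=pixels_x,
        pixels_y=pixels_y,
    )


def segment(image: SEMImage, threshold: float | str = "auto") -> SegmentationResult:
    """Threshold-segment particle pixels (strictly ``intensity > threshold``).

    ``threshold="auto"`` picks the threshold by between-class variance
    maximization (Otsu) on the intensity histogram; a constant image cannot
    be auto-thresholded and raises instead.
    """
    data = np.asarray(image.intensities)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be a number or 'auto', got {threshold!r}")
        if data.size == 0 or data.min() == data.max():
            raise ValueError(
                "constant image: automatic thresholding is undefined; "
                "pass an explicit threshold"
            )
        threshold_value = float(threshold_otsu(data))
    else:
        threshold_value = float(threshold)
        if not 0 <= threshold_value <= image.max_intensity:
            raise ValueError(
                f"threshold {threshold_value} outside [0, {image.max_intensity}] "
                f"for a {image.bit_depth}-bit image"
            )
    mask = data > threshold_value
    count = int(mask.sum())
    return SegmentationResult(
        mask=mask,
        threshold_used=threshold_value,
        np_pixel_count=count,
        total_np_area_um2=count * image.calibration.pixel_area_um2,
        calibration=image.calibration,
    )


def dose_from_segmentation(
    seg: SegmentationResult, particle: ParticleSpec, exposure: ExposureSpec
) -> DoseEstimate:
    """Convert a segmentation to a DoseEstimate against the nominal dose."""
    measured = area_to_dose(
        seg.total_np_area_um2, particle, seg.calibration.field_area_um2
    )
    return DoseEstimate(
        measured_dose_ug_cm2=measured,
        nominal_dose_ug_cm2=nominal_dose(exposure),
    )


def estimate_dose(
    image: SEMImage,
    threshold: float | str,
    particle: ParticleSpec,
    exposure: ExposureSpec,
) -> DoseEstimate:
    """segment → occupied area → areal dose → efficiency, in one call."""
    return dose_from_segmentation(segment(image, threshold), particle, exposure)


def aggregate_stats(seg: SegmentationResult, particle: ParticleSpec) -> AggregateStats:
    """Summarize aggregation by 8-connected components of the mask.

    The single-particle cutoff is 2 × (π d²/4): components above it are
    counted as aggregates (either laterally merged particles or genuine
    clusters).  Component areas always sum to the total occupied area.
    """
    labels = label(seg.mask, connectivity=2)
    areas_um2 = np.array(
        [p.area * seg.calibration.pixel_area_um2 for p in regionprops(labels)]
    )
    if areas_um2.size == 0:
        return AggregateStats(
            n_components=0,
            component_areas_um2=areas_um2,
            largest_component_area_um2=0.0,
            aggregate_area_fraction=0.0,
        )
    cutoff_um2 = 2.0 * units.nm2_to_um2(particle.projected_area_nm2)
    total = areas_um2.sum()
    aggregated = areas_um2[areas_um2 > cutoff_um2].sum()
    return AggregateStats(
        n_components=int(areas_um2.size),
        component_areas_um2=areas_um2,
        largest_component_area_um2=float(areas_um2.max()),
        aggregate_area_fraction=float(aggregated / total) if total > 0 else 0.0,
    )
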