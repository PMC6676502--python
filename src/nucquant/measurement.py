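"""Query-channel measurement with background subtraction.

ROIs found on the marker channel are superimposed onto the query channel
(e.g. a phosphorylated Smad stain), mean pixel intensity is collected per
ROI, a single background level is estimated from the in-selection pixels
that belong to no ROI, and the background is subtracted from every ROI mean.
The background-subtracted mean is the quantity compared between genotypes.

Design notes: the background statistic is the arithmetic mean by default
(a median option is available); one global background value is used per
image, not per-ROI annuli; negative corrected means are reported and
flagged, never clipped, because clipping would bias fold-change statistics;
the image-level summary is the unweighted mean over ROIs (each nucleus is
one biological observation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import ChannelImage
from .segmentation import (
    BinaryMask,
    Particle,
    ParticleFilter,
    SelectionRegion,
    ThresholdSpec,
    analyze_particles,
    apply_threshold,
    auto_threshold,
    binary_dilate,
    binary_watershed,
    clear_outside_selection,
    edit_particles,
)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class MaskPair:
    """Exact partition of the in-selection pixels.

    ``measurement_mask`` is the union of all particle pixel sets (within the
    selection); ``background_mask`` is every other in-selection pixel.  The
    two masks are disjoint and their union equals the selection.
    """

    measurement_mask: BinaryMask
    background_mask: BinaryMask


@dataclass
class QuantResult:
    """Background-subtracted intensity of one ROI on the query channel.

    ``mean_corrected = mean_raw - mean_bg`` exactly; it may be negative, in
    which case ``negative_flag`` is set.  ``integrated_density`` is the
    optional mean x area product.
    """

    image_id: str
    roi_id: int
    area_px: int
    mean_raw: float
    mean_bg: float
    mean_corrected: float
    centroid: tuple[float, float]

    @property
    def negative_flag(self) -> bool:
        return self.mean_corrected < 0

    @property
    def integrated_density(self) -> float:
        return self.mean_raw * self.area_px


@dataclass
class ImageSummary:
    """Per-image roll-up: unweighted mean of corrected ROI means."""

    image_id: str
    n_rois: int
    mean_corrected_mean: float
    mean_bg: float
    mean_raw_mean: float


def build_masks(
    particles: Sequence[Particle],
    selection: SelectionRegion,
    shape: tuple[int, int],
) -> MaskPair:
    """Build the measurement/background partition of the selection."""
    sel = selection.to_mask(shape)
    union = np.zeros(shape, dtype=bool)
    for p in particles:
        union[p.coords[:, 0], p.coords[:, 1]] = True
    measurement = union & sel
    background = sel & ~union
    return MaskPair(BinaryMask(measurement), BinaryMask(background))


def measure_rois(
    query: ChannelImage, particles: Sequence[Particle]
) -> list[tuple[int, float, int, tuple[float, float]]]:
    """Mean query intensity over each particle's pixel set, double precision.

    Returns ``(roi_id, mean_raw, area, centroid)`` tuples.
    """
    vals = query.values
    out = []
    for p in particles:
        if p.coords[:, 0].max() >= vals.shape[0] or p.coords[:, 1].max() >= vals.shape[1]:
            raise ValueError(
                "particle pixels fall outside the query channel; marker and "
                "query dimensions must match"
            )
        mean_raw = float(vals[p.coords[:, 0], p.coords[:, 1]].astype(np.float64).mean())
        out.append((p.label, mean_raw, p.area, p.centroid))
    return out


def measure_background(
    query: ChannelImage, masks: MaskPair, statistic: str = "mean"
) -> float:
    """Background level of the query channel over the background mask."""
    bg = masks.background_mask.values
    if not bg.any():
        raise ValueError(
            "background mask is empty (ROIs tile the whole selection); use "
            "smaller particles or a larger selection"
        )
    pixels = query.values[bg].astype(np.float64)
    if statistic == "mean":
        return float(pixels.mean())
    if statistic == "median":
        return float(np.median(pixels))
    raise ValueError(f"unknown background statistic {statistic!r}")


def quantify_image(
    marker: ChannelImage,
    query: ChannelImage,
    selection: SelectionRegion | None = None,
    tspec: ThresholdSpec | None = None,
    pfilter: ParticleFilter | None = None,
    include_ids: Sequence[int] = (),
    exclude_ids: Sequence[int] = (),
    image_id: str | None = None,
    background_statistic: str = "mean",
    auto_method: str = "default",
) -> tuple[list[QuantResult], ImageSummary]:
    """Run the full single-image pipeline.

    Stages: clear outside selection -> threshold (auto when ``tspec`` is
    None) -> optional dilate -> optional watershed -> particle analysis ->
    ROI edits -> mask building -> measurement with background subtraction.
    Stage failures are re-raised as :class:`StageError` naming the stage.
    """
    if marker.shape != query.shape:
        raise ValueError(
            f"marker {marker.shape} and query {query.shape} dimensions differ"
        )
    selection = selection or SelectionRegion.whole_image()
    pfilter = pfilter or ParticleFilter()
    image_id = image_id or (marker.source_path or "image")

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - stage name attached
            raise StageError(name, exc) from exc

    cleared = _stage("clear_selection", clear_outside_selection, marker, selection)
    if tspec is None:
        tspec = _stage("auto_threshold", auto_threshold, cleared, selection, auto_method)
    mask = _stage("threshold", apply_threshold, cleared, tspec, selection)
    if pfilter.apply_dilate:
        mask = _stage("dilate", binary_dilate, mask, pfilter.dilate_iterations)
    if pfilter.apply_watershed:
        mask = _stage("watershed", binary_watershed, mask)
    particles = _stage("analyze_particles", analyze_particles, mask, pfilter)
    particles = _stage("edit_particles", edit_particles, particles, include_ids, exclude_ids)
    masks = _stage("build_masks", build_masks, particles, selection, marker.shape)

    results: list[QuantResult] = []
    if particles:
        mean_bg = _stage(
            "measure_background", measure_background, query, masks, background_statistic
        )
        measured = _stage("measure_rois", measure_rois, query, particles)
        for roi_id, mean_raw, area, centroid in measured:
            results.append(
                QuantResult(
                    image_id=image_id,
                    roi_id=roi_id,
                    area_px=area,
                    mean_raw=mean_raw,
                    mean_bg=mean_bg,
                    mean_corrected=mean_raw - mean_bg,
                    centroid=centroid,
                )
            )
        summary = ImageSummary(
            image_id=image_id,
            n_rois=len(results),
            mean_corrected_mean=float(np.mean([r.mean_corrected for r in results])),
            mean_bg=mean_bg,
            mean_raw_mean=float(np.mean([r.mean_raw for r in results])),
        )
    else:
        summary = ImageSummary(
            image_id=image_id,
            n_rois=0,
            mean_corrected_mean=float("nan"),
            mean_bg=float("nan"),
            mean_raw_mean=float("nan"),
        )
    return results, summary
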