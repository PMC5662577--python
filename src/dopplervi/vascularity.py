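"""Color-pixel classification and vascular index (VI) computation.

The vascular index of a region is the percentage of color-coded (flow)
pixels among all pixels of the region.  A pixel is *color* when its RGB
channel spread ``max(R,G,B) - min(R,G,B)`` exceeds a threshold tau;
grey-scale tissue has R=G=B exactly in lossless scanner output, so the
default tau is 0.  For images that passed through a lossy pipeline at
some point, tau of 10-20 absorbs chroma noise (at the cost of missing
the faintest flow pixels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyRegionError, ValidationError
from .geometry import OffsetMode, RegionPartition, inward_offset
from .image_io import AnnotatedImage, ROIMask


@dataclass(frozen=True)
class ColorMask:
    """Boolean raster of color-coded flow pixels (inside the ROI only)."""

    grid: np.ndarray
    spread_threshold: float

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class VascularProfile:
    """Overall / peripheral / central VI of one nodule at one offset.

    A regional VI is ``None`` when its region is empty (e.g. the central
    region at an offset beyond the inradius, or the peripheral region at
    offset 0) — never coerced to 0, which would bias cohort statistics.
    """

    overall_vi: float
    peripheral_vi: float | None
    central_vi: float | None
    offset_pct: float
    source_image_id: str | None = None
    roi_area_px: int = 0
    central_area_px: int = 0
    color_px_total: int = 0


def classify_color_pixels(
    image: AnnotatedImage, mask: ROIMask, tau: float = 0.0
) -> ColorMask:
    """Flow pixels inside *mask*: channel spread strictly above *tau*."""
    if tau < 0:
        raise ValidationError(f"tau must be >= 0, got {tau}")
    if image.pixels.shape[:2] != mask.shape:
        raise ValidationError(
            f"image shape {image.pixels.shape[:2]} does not match mask "
            f"shape {mask.shape}"
        )
    px = image.pixels.astype(np.int16)
    spread = px.max(axis=2) - px.min(axis=2)
    return ColorMask(grid=(spread > tau) & mask.grid, spread_threshold=float(tau))


def vascular_index(color: ColorMask, region: ROIMask) -> float:
    """VI of *region* in percent: 100 x (color pixels in region) / (region area).

    Both counts are integers, so the quotient is exact up to the final
    floating-point representation.
    """
    if color.grid.shape != region.shape:
        raise ValidationError("color mask and region have different shapes")
    n = region.pixel_count
    if n == 0:
        raise EmptyRegionError("vascular index of an empty region is undefined")
    return 100.0 * int((color.grid & region.grid).sum()) / n


def profile_nodule(
    image: AnnotatedImage,
    mask: ROIMask,
    offset_pct: float,
    tau: float = 0.0,
    mode: OffsetMode = "erosion",
) -> VascularProfile:
    """Partition the nodule at *offset_pct* and compute its three VIs.

    The exact count identity ``color(overall) = color(peripheral) +
    color(central)`` holds by construction, so the overall VI is the
    area-weighted mean of the regional VIs.
    """
    part = inward_offset(mask, offset_pct, mode=mode)
    color = classify_color_pixels(image, mask, tau)
    return profile_from_partition(color, part, source_image_id=image.image_id)


def profile_from_partition(
    color: ColorMask, part: RegionPartition, source_image_id: str | None = None
) -> VascularProfile:
    """Assemble a :class:`VascularProfile` from a precomputed partition."""

    def _vi(region: ROIMask) -> float | None:
        return None if region.is_empty() else vascular_index(color, region)

    overall = vascular_index(color, part.primary)
    return VascularProfile(
        overall_vi=overall,
        peripheral_vi=_vi(part.peripheral),
        central_vi=_vi(part.central),
        offset_pct=part.offset_pct,
        source_image_id=source_image_id,
        roi_area_px=part.primary.pixel_count,
        central_area_px=part.central.pixel_count,
        color_px_total=int((color.grid & part.primary.grid).sum()),
    )


def select_representative_image(
    profiles: Sequence[VascularProfile],
) -> VascularProfile:
    """Of several frames of one nodule, keep the one with the highest
    overall VI; ties go to the earliest acquisition."""
    if len(profiles) == 0:
        raise ValidationError("no profiles to select from")
    return max(profiles, key=lambda p: p.overall_vi)  # max keeps the first tie
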