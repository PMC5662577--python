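"""Reading annotated sonograms and recovering the nodule ROI.

The clinical workflow this package supports is: an operator outlines a
thyroid nodule on a still color Doppler frame with a single solid color,
saves the image losslessly, and the software recovers the *primary ROI*
(the filled nodule region) from that outline.  This module owns the two
raster types involved — :class:`AnnotatedImage` and :class:`ROIMask` —
plus lossless image/mask I/O.

Conventions
-----------
* 0-based pixel indexing, row-major, origin at the top-left corner.
* Areas are pixel counts; distances are Euclidean distances between
  pixel centers, in pixel units.
* The annotation color defaults to pure green ``(0, 255, 0)``: grey-scale
  tissue has R=G=B and standard Doppler color maps occupy red/yellow and
  blue/cyan hues, so pure green cannot collide with either.  Matching is
  *exact* — lossy-compressed inputs smear the outline color and are
  rejected at read time (use PNG or TIFF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage as ndi

from .errors import (
    AmbiguousOutlineError,
    InputFormatError,
    MissingOutlineError,
    OpenContourError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default RGB triple used to mark the hand-drawn nodule outline.
DEFAULT_ANNOTATION_COLOR: tuple[int, int, int] = (0, 255, 0)

#: Formats accepted for annotated input (lossless only).
LOSSLESS_FORMATS = frozenset({"PNG", "TIFF"})

#: 4-connectivity structuring element (shared by flood fill and labelling).
_CROSS = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class AnnotatedImage:
    """An 8-bit RGB ultrasound still with a known outline color.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` uint8 array, exactly as decoded — no
        resampling and no color conversion beyond forcing RGB.
    annotation_color
        Exact RGB triple used for the manual outline.
    image_id
        Optional identifier (defaults to the source file stem when read
        from disk); used by representative-image selection.
    """

    pixels: np.ndarray
    annotation_color: tuple[int, int, int] = DEFAULT_ANNOTATION_COLOR
    image_id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"expected an (H, W, 3) RGB array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ValidationError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have height >= 1 and width >= 1")
        c = tuple(int(v) for v in self.annotation_color)
        if len(c) != 3 or any(v < 0 or v > 255 for v in c):
            raise ValidationError(f"annotation color {c!r} is not an RGB triple")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "annotation_color", c)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class ROIMask:
    """A binary raster region (same shape as its source image).

    A *valid nodule* mask is non-empty, 4-connected and free of interior
    holes; :meth:`validate_nodule` checks all three.  Derived regions
    (e.g. the central region at a large offset) may legitimately be
    empty, so emptiness is not rejected at construction.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {g.shape}")
        if g.dtype != bool:
            g = g.astype(bool)
        object.__setattr__(self, "grid", g)

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def is_empty(self) -> bool:
        return not self.grid.any()

    def validate_nodule(self) -> "ROIMask":
        """Assert the invariants of a primary (whole-nodule) ROI."""
        if self.is_empty():
            raise ValidationError("nodule mask is empty")
        _, n_comp = ndi.label(self.grid, structure=_CROSS)
        if n_comp != 1:
            raise ValidationError(
                f"nodule mask has {n_comp} 4-connected components, expected 1"
            )
        if np.any(ndi.binary_fill_holes(self.grid) != self.grid):
            raise ValidationError("nodule mask has interior holes")
        return self


def read_annotated_image(
    path: str | Path,
    annotation_color: tuple[int, int, int] = DEFAULT_ANNOTATION_COLOR,
) -> AnnotatedImage:
    """Read a lossless 8-bit RGB(-convertible) image from *path*.

    Raises
    ------
    OSError
        If the file does not exist or cannot be opened.
    InputFormatError
        If the file is not an image, is truncated, uses a lossy format,
        or has an unsupported bit depth.
    """
    path = Path(path)
    try:
        im = Image.open(path)
    except UnidentifiedImageError as exc:
        raise InputFormatError(f"{path}: not a recognised image file") from exc
    with im:
        fmt = im.format
        if fmt not in LOSSLESS_FORMATS:
            raise InputFormatError(
                f"{path}: format {fmt!r} is not supported; exact-color outline "
                f"recovery requires a lossless format (PNG or TIFF)"
            )
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise InputFormatError(
                f"{path}: unsupported bit depth (mode {im.mode!r}); "
                f"8-bit per channel required"
            )
        try:
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
        except OSError as exc:  # truncated / corrupt payload
            raise InputFormatError(f"{path}: could not decode image data") from exc
    return AnnotatedImage(pixels, annotation_color, image_id=path.stem)


def write_image(image: AnnotatedImage, path: str | Path) -> None:
    """Write an :class:`AnnotatedImage` losslessly (PNG or TIFF by suffix)."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path)


def extract_roi_from_outline(
    image: AnnotatedImage, *, select_largest: bool = False
) -> ROIMask:
    """Recover the filled nodule interior from the hand-drawn outline.

    The background is flood-filled from every border pixel with
    4-connectivity, treating outline-colored pixels as barriers; the
    interior is whatever remains (neither outline nor background).  This
    is robust to concave outlines and to outline strokes thicker than one
    pixel.  Enclosed background islands are filled into the mask, so the
    primary ROI is simply connected — the nodule is a solid region and
    the vascular index is computed over its whole area.

    Outline pixels themselves are *excluded* from the mask.

    Parameters
    ----------
    select_largest
        With several disjoint closed outlines in one frame, pick the one
        with the largest interior instead of raising
        :class:`AmbiguousOutlineError`.
    """
    outline = np.all(image.pixels == np.array(image.annotation_color), axis=-1)
    if not outline.any():
        raise MissingOutlineError(
            f"no pixel matches annotation color {image.annotation_color}"
        )

    free = ~outline
    labels, _ = ndi.label(free, structure=_CROSS)
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border_labels = border_labels[border_labels != 0]
    interior = free & ~np.isin(labels, border_labels)
    if not interior.any():
        raise OpenContourError(
            "outline is not closed: flood fill from the border reached "
            "every non-outline pixel"
        )

    comp_labels, n_comp = ndi.label(interior, structure=_CROSS)
    if n_comp > 1:
        sizes = ndi.sum_labels(interior, comp_labels, index=range(1, n_comp + 1))
        if not select_largest:
            raise AmbiguousOutlineError(
                f"{n_comp} disjoint closed outlines found (interior sizes "
                f"{[int(s) for s in sizes]}); pass select_largest=True to keep "
                f"the largest"
            )
        keep = 1 + int(np.argmax(sizes))
        interior = comp_labels == keep
        logger.info("selected largest of %d outlined regions", n_comp)

    mask = ndi.binary_fill_holes(interior) & ~outline
    return ROIMask(mask).validate_nodule()


def read_mask(path: str | Path) -> ROIMask:
    """Read a binary region mask (any image binarizable at 50% grey).

    Multi-channel inputs are converted to luminance first; pixels above
    mid-grey are inside.
    """
    path = Path(path)
    try:
        im = Image.open(path)
    except UnidentifiedImageError as exc:
        raise InputFormatError(f"{path}: not a recognised image file") from exc
    with im:
        grey = np.asarray(im.convert("L"))
    grid = grey > 127
    if not grid.any():
        raise ValidationError(f"{path}: mask is empty")
    return ROIMask(grid)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    """Write a mask as single-channel PNG: 0 = outside, 255 = inside."""
    arr = np.where(mask.grid, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))
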