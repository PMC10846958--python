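"""Collagen fibre densitometry from polarized-light histology images.

Under crossed polarizers Picrosirius-Red-stained collagen is birefringent
and appears bright on a dark background.  Collagen fibre density of a
region of interest is the percentage of pixels at or above an 8-bit
intensity threshold (default 75/255) after greyscale conversion.

Coordinate convention: micrometres, origin at the top-left image corner,
y pointing down; a pixel (row r, col c) has its centre at
((c + 0.5) * pitch, (r + 0.5) * pitch).  ROI boxes are half-open,
[x, x + side) x [y, y + side), membership by pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray

from .errors import FormatError, RoiBoundsError


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned square ROI in image coordinates (um)."""

    roi_id: str
    x_um: float
    y_um: float
    side_um: float = 50.0

    def __post_init__(self) -> None:
        if not self.side_um > 0:
            raise ValueError(f"{self.roi_id}: side_um must be positive")

    @property
    def corners_um(self) -> np.ndarray:
        """Corners (4, 2) as (x, y), order TL, TR, BR, BL."""
        x, y, s = self.x_um, self.y_um, self.side_um
        return np.array([[x, y], [x + s, y], [x + s, y + s], [x, y + s]])


@dataclass(frozen=True)
class CollagenRoi:
    """Fibre density of one ROI."""

    roi_id: str
    density_pct: float
    threshold_used: int | None = None


def roi_pixel_slices(box: RoiBox, pixel_pitch_um: float, shape: tuple[int, int]) -> tuple[slice, slice]:
    """Row/column slices of the pixels whose centres fall inside ``box``.

    Shared by the densitometry and the synthetic image generator so the
    two always agree on ROI membership.
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    p = pixel_pitch_um
    c0 = int(np.ceil(box.x_um / p - 0.5))
    c1 = int(np.ceil((box.x_um + box.side_um) / p - 0.5))
    r0 = int(np.ceil(box.y_um / p - 0.5))
    r1 = int(np.ceil((box.y_um + box.side_um) / p - 0.5))
    if c0 < 0 or r0 < 0 or c1 > shape[1] or r1 > shape[0]:
        raise RoiBoundsError(f"ROI {box.roi_id!r} falls outside the image")
    if c1 <= c0 or r1 <= r0:
        raise RoiBoundsError(f"ROI {box.roi_id!r} contains no pixel centres")
    return slice(r0, r1), slice(c0, c1)


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit image to single-channel 8-bit greyscale.

    Greyscale input passes through unchanged; RGB(A) is converted with
    standard luminance weights (ITU-R 601, via scikit-image).
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {image.dtype}")
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        grey = rgb2gray(image[..., :3])  # float in [0, 1]
        return np.round(grey * 255.0).astype(np.uint8)
    raise FormatError(f"unsupported image shape {image.shape}")


def binarize(image: np.ndarray, threshold: int = 75) -> np.ndarray:
    """Boolean mask: pixel >= threshold -> white (collagen)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise FormatError("binarize expects a single-channel image")
    return image >= threshold


def roi_density(
    mask: np.ndarray,
    box: RoiBox,
    pixel_pitch_um: float,
    threshold_used: int | None = None,
) -> CollagenRoi:
    """Percentage of white pixels within ``box``."""
    rows, cols = roi_pixel_slices(box, pixel_pitch_um, mask.shape)
    sub = np.asarray(mask, dtype=bool)[rows, cols]
    return CollagenRoi(
        roi_id=box.roi_id,
        density_pct=100.0 * float(sub.mean()),
        threshold_used=threshold_used,
    )


def measure_rois(
    image: np.ndarray,
    boxes: list[RoiBox],
    pixel_pitch_um: float,
    threshold: int = 75,
) -> list[CollagenRoi]:
    """Greyscale -> binarize -> per-ROI density for a batch of boxes."""
    mask = binarize(to_greyscale(image), threshold)
    return [roi_density(mask, b, pixel_pitch_um, threshold_used=threshold) for b in boxes]


def calibrate_threshold(
    image: np.ndarray,
    reference_mask: np.ndarray,
    reference_density_pct: float,
) -> int:
    """Threshold whose white fraction over the reference region best
    matches an externally measured collagen density.

    Scans all 256 levels; ties break toward the lower threshold.  The
    reference value comes from an independent modality (e.g. second
    harmonic generation imaging of the medial layer) and is a required
    input, not a constant of this package.
    """
    if not 0.0 < reference_density_pct <= 100.0:
        raise ValueError("reference density must be in (0, 100]")
    grey = to_greyscale(image)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != grey.shape:
        raise FormatError("reference mask shape does not match image")
    values = grey[reference_mask]
    if values.size == 0:
        raise ValueError("empty reference region")
    hist = np.bincount(values.ravel(), minlength=256)
    at_or_above = np.cumsum(hist[::-1])[::-1]  # at_or_above[t] = #pixels >= t
    density = 100.0 * at_or_above / values.size
    return int(np.argmin(np.abs(density - reference_density_pct)))
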