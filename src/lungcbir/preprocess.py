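"""Lung-parenchyma extraction from a raw CT slice.

The pipeline is the classical one: threshold the slice at an air/tissue
Hounsfield cutoff, remove the exterior air by seed-filling from the image
border, drop speck-sized components, and close internal hollows (vessels
and fibrous texture make the lung field "hollow" relative to its outline)
with a disc-shaped structuring element. ``apply_mask`` then blanks
everything outside the lung field so the detail network sees only the
parenchymal content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing, disk

DEFAULT_THRESHOLD_HU = -320.0
#: minimum lung-candidate component area as a fraction of the image area
MIN_COMPONENT_FRACTION = 0.005


class ValidationError(ValueError):
    pass


@dataclass
class LungMask:
    """Binary lung-field mask aligned with its source slice."""

    mask: np.ndarray
    threshold_hu: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def binarize_hu(slice_hu: np.ndarray, threshold_hu: float = DEFAULT_THRESHOLD_HU) -> np.ndarray:
    """Return 1 where the slice is air-like (intensity < threshold), else 0."""
    arr = np.asarray(slice_hu, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("slice contains non-finite intensities")
    return (arr < threshold_hu).astype(np.uint8)


def default_closing_radius(image_size: int) -> int:
    """Closing-disc radius, 7 px at 512 resolution, scaled proportionally."""
    return max(1, int(np.ceil(7 * image_size / 512)))


def structure_closing_radius(image_size: int) -> int:
    """Closing-disc radius scaled to nodule-size structures (size/16).

    The vessel-scale default above fills fibrous texture; enclosed
    nodule-scale structures punch larger holes in the air-threshold
    mask and need a correspondingly larger disc to be reclaimed into
    the lung field.
    """
    return max(1, int(np.ceil(image_size / 16)))


def _border_connected(binary: np.ndarray) -> np.ndarray:
    """Pixels 4-connected to the image border through the foreground.

    This is the seed-filling step: flooding from every border pixel labels
    the exterior air, which is everything reachable from the frame.
    """
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    labels, _ = ndimage.label(binary, structure=structure)
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border_labels = border_labels[border_labels != 0]
    return np.isin(labels, border_labels)


def extract_lung_mask(binary: np.ndarray, closing_radius: int | None = None,
                      min_area_fraction: float = MIN_COMPONENT_FRACTION) -> LungMask:
    """Separate interior air (lung) from exterior air and close hollows.

    Steps: (1) remove the border-connected exterior; (2) keep remaining
    air components above the minimum area; (3) morphological closing with
    a disc to fill internal hollows. An empty result is returned as an
    empty mask with a warning, never as an exception.
    """
    binary = np.asarray(binary).astype(bool)
    if closing_radius is None:
        closing_radius = default_closing_radius(max(binary.shape))

    interior = binary & ~_border_connected(binary)

    structure = ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(interior, structure=structure)
    min_area = min_area_fraction * binary.size
    keep = np.zeros_like(interior)
    if n:
        areas = ndimage.sum_labels(interior, labels, index=np.arange(1, n + 1))
        good = np.flatnonzero(areas >= min_area) + 1
        keep = np.isin(labels, good)

    if not keep.any():
        warnings.warn("lung mask is empty after exterior removal and area filtering",
                      stacklevel=2)
        return LungMask(mask=keep, threshold_hu=np.nan)

    closed = _closing(keep, disk(closing_radius))
    return LungMask(mask=closed, threshold_hu=np.nan)


def segment_lungs(slice_hu: np.ndarray, threshold_hu: float = DEFAULT_THRESHOLD_HU,
                  closing_radius: int | None = None) -> LungMask:
    """binarize_hu + extract_lung_mask in one call."""
    mask = extract_lung_mask(binarize_hu(slice_hu, threshold_hu), closing_radius)
    mask.threshold_hu = threshold_hu
    return mask


def apply_mask(slice_hu: np.ndarray, mask: LungMask | np.ndarray,
               fill_value: float = -1000.0) -> np.ndarray:
    """Keep intensities inside the mask; set the outside to ``fill_value``."""
    arr = np.asarray(slice_hu, dtype=float)
    m = mask.mask if isinstance(mask, LungMask) else np.asarray(mask).astype(bool)
    if m.shape != arr.shape:
        raise ValidationError(f"mask shape {m.shape} != slice shape {arr.shape}")
    return np.where(m, arr, fill_value)


def mask_case(slices: list[np.ndarray], threshold_hu: float = DEFAULT_THRESHOLD_HU,
              closing_radius: int | None = None,
              fill_value: float = -1000.0) -> list[np.ndarray]:
    """Segment and mask every slice of a case stack."""
    out = []
    for s in slices:
        r = closing_radius if closing_radius is not None \
            else structure_closing_radius(max(np.asarray(s).shape))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = segment_lungs(s, threshold_hu, r)
        out.append(apply_mask(s, m, fill_value))
    return out
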