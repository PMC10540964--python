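"""Spatial transformation layer: thin-plate-spline warps driven by a 5x5
control grid.

The warp is defined by a 25x2 control tensor of displacements in the
normalized [-1, 1] image coordinate system. A grid generator interpolates
the control displacements over the whole pixel grid with a thin-plate
spline (the natural interpolant for scattered 2-D displacements), and a
bilinear sampler reads the input image at the displaced coordinates,
taking the border value outside the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import map_coordinates

N_CONTROL = 25  # 5x5 grid
MAX_MAGNITUDE = 0.2


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ControlTensor:
    """25 control-point displacements in normalized [-1, 1] coordinates."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.theta, dtype=float)
        if arr.shape != (N_CONTROL, 2):
            raise ValidationError(f"theta must be {N_CONTROL}x2, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("theta contains non-finite entries")
        object.__setattr__(self, "theta", arr)

    @staticmethod
    def zeros() -> "ControlTensor":
        return ControlTensor(np.zeros((N_CONTROL, 2)))


def control_grid() -> np.ndarray:
    """The fixed 5x5 control-point layout in normalized coordinates."""
    axis = np.linspace(-1.0, 1.0, 5)
    rr, cc = np.meshgrid(axis, axis, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def sample_theta(magnitude: float, seed: int) -> ControlTensor:
    """Draw a random control tensor, each component uniform in
    [-magnitude, magnitude], clipped to the normalized range."""
    if not (0.0 <= magnitude <= MAX_MAGNITUDE):
        raise ValidationError(f"magnitude must be in [0, {MAX_MAGNITUDE}], got {magnitude}")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-magnitude, magnitude, size=(N_CONTROL, 2))
    return ControlTensor(np.clip(theta, -1.0, 1.0))


def stl_warp(image: np.ndarray, theta: ControlTensor | np.ndarray) -> np.ndarray:
    """Warp an image with the thin-plate-spline field of a control tensor.

    For every output pixel the grid generator produces a source coordinate
    (pixel position plus the TPS-interpolated displacement); the sampler
    bilinearly interpolates the input there, clamping to the border.
    """
    if not isinstance(theta, ControlTensor):
        theta = ControlTensor(np.asarray(theta))
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValidationError("image must be 2-D and at least 8x8")

    if not theta.theta.any():
        return img.copy()

    h, w = img.shape
    # grid generator: TPS interpolation of the 25 displacements
    interp = RBFInterpolator(control_grid(), theta.theta,
                             kernel="thin_plate_spline", degree=1)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    norm = np.stack([2 * rr.ravel() / (h - 1) - 1, 2 * cc.ravel() / (w - 1) - 1], axis=1)
    disp = interp(norm)
    src_r = rr.ravel() + disp[:, 0] * (h - 1) / 2.0
    src_c = cc.ravel() + disp[:, 1] * (w - 1) / 2.0
    # sampler: bilinear, border value outside
    out = map_coordinates(img, np.stack([src_r, src_c]), order=1, mode="nearest")
    return out.reshape(h, w)
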