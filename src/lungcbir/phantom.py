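"""Synthetic lung-CT phantom generator.

Produces ordered stacks of 2-D slices that mimic the gross structure of a
thoracic CT at the level needed by the downstream similarity pipeline: an
air background (~ -1000 HU), a soft-tissue thorax disc (~ 0 HU), two
parenchymal lung lobes (~ -700 HU) whose outlines change smoothly from
slice to slice, and bright internal "white stripes" (vessel- and
nodule-like structures) that drift gently through the stack.

Everything is deterministic given ``(config.seed, case_seed)`` so that
every downstream stage is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a phantom configuration violates its invariants."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic case generator.

    Intensities are in Hounsfield units; ``stripe_drift`` is the maximum
    per-slice displacement of a stripe centre, in pixels.
    """

    image_size: int = 64
    n_slices: int = 20
    n_cases: int = 6
    hu_air: float = -1000.0
    hu_parenchyma: float = -700.0
    hu_tissue: float = 0.0
    stripe_count_range: Tuple[int, int] = (3, 7)
    stripe_drift: float = 1.5
    noise_sigma: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.n_slices < 3:
            raise ConfigurationError("n_slices must be >= 3")
        if not (self.hu_air < self.hu_parenchyma < self.hu_tissue):
            raise ConfigurationError("need hu_air < hu_parenchyma < hu_tissue")
        lo, hi = self.stripe_count_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("stripe_count_range must be 0 <= lo <= hi")
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        if self.stripe_drift < 0:
            raise ConfigurationError("stripe_drift must be >= 0")


@dataclass
class CaseSeries:
    """One patient's ordered slice stack.

    The slice order index is the "layer" used by the weak-labelling rules:
    adjacent layers are detail-similar, distant layers contour-dissimilar.
    """

    case_id: str
    slices: List[np.ndarray]
    spacing: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices of case {self.case_id!r} differ in shape: {shapes}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def stack(self) -> np.ndarray:
        return np.stack(self.slices, axis=0)


def _ellipse_mask(size: int, center: Tuple[float, float], axes: Tuple[float, float],
                  angle: float = 0.0) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _disc_mask(size: int, center: Tuple[float, float], radius: float) -> np.ndarray:
    return _ellipse_mask(size, center, (radius, radius))


def _polyline_mask(size: int, points: np.ndarray, thickness: float) -> np.ndarray:
    """Rasterize a thick polyline: pixels within `thickness` of any segment."""
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    mask = np.zeros((size, size), dtype=bool)
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        dr, dc = r1 - r0, c1 - c0
        seg2 = dr * dr + dc * dc
        if seg2 == 0:
            t = np.zeros_like(rr)
        else:
            t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / seg2, 0.0, 1.0)
        d2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
        mask |= d2 <= thickness ** 2
    return mask


def _case_geometry(config: PhantomConfig, rng: np.random.Generator) -> dict:
    """Draw per-case anatomy: lobe profiles and stripe tracks.

    Lobe axes grow monotonically with the slice index (plus a small smooth
    modulation), so slices farther apart in the stack always differ more —
    the property the weak-labelling rules rely on.
    """
    s = config.image_size
    n = config.n_slices
    r = np.arange(n) / max(n - 1, 1)

    thorax_radius = 0.46 * s
    base_a = s * rng.uniform(0.26, 0.30)   # lobe semi-axis, rows
    base_b = s * rng.uniform(0.13, 0.16)   # lobe semi-axis, cols
    growth = rng.uniform(0.25, 0.40)       # monotone axis growth over the stack
    wobble = 0.04 * np.sin(2 * np.pi * r + rng.uniform(0, 2 * np.pi))
    profile = (0.65 + growth * r) * (1.0 + wobble)

    n_stripes = int(rng.integers(config.stripe_count_range[0],
                                 config.stripe_count_range[1] + 1))
    stripes = []
    for _ in range(n_stripes):
        side = rng.integers(0, 2)          # which lobe
        kind = "disc" if rng.random() < 0.6 else "line"
        # start near the lobe centre, in lobe-relative coordinates
        rel = rng.uniform(-0.45, 0.45, size=2)
        steps = rng.uniform(-1.0, 1.0, size=(n, 2)) * config.stripe_drift
        steps[0] = 0.0
        track = np.cumsum(steps, axis=0)
        z0 = int(rng.integers(0, max(1, n // 4)))
        z1 = int(rng.integers(n - max(1, n // 4), n)) + 1
        stripes.append({
            "side": int(side), "kind": kind, "rel": rel, "track": track,
            "radius": float(rng.uniform(0.025, 0.055) * s),
            "length": float(rng.uniform(0.10, 0.22) * s),
            "angle": float(rng.uniform(0, np.pi)),
            "z_range": (z0, z1),
        })
    return {
        "thorax_radius": thorax_radius,
        "base_axes": (base_a, base_b),
        "profile": profile,
        "stripes": stripes,
    }


def lobe_centers(size: int) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Row/col centres of the two lung lobes, left and right of the midline."""
    return (size / 2.0, size * 0.33), (size / 2.0, size * 0.67)


def render_slice(config: PhantomConfig, geom: dict, index: int,
                 with_noise: bool = True,
                 noise_rng: np.random.Generator | None = None) -> np.ndarray:
    s = config.image_size
    img = np.full((s, s), config.hu_air, dtype=float)
    center = (s / 2.0, s / 2.0)
    thorax = _disc_mask(s, center, geom["thorax_radius"])
    img[thorax] = config.hu_tissue

    a, b = geom["base_axes"]
    scale = geom["profile"][index]
    lobes = np.zeros((s, s), dtype=bool)
    for lc in lobe_centers(s):
        lobes |= _ellipse_mask(s, lc, (a * scale, b * scale)) & thorax
    img[lobes] = config.hu_parenchyma

    for stripe in geom["stripes"]:
        z0, z1 = stripe["z_range"]
        if not (z0 <= index < z1):
            continue
        lc = lobe_centers(s)[stripe["side"]]
        pos = np.array([lc[0] + stripe["rel"][0] * a, lc[1] + stripe["rel"][1] * 2 * b])
        pos = pos + stripe["track"][index]
        if stripe["kind"] == "disc":
            m = _disc_mask(s, tuple(pos), stripe["radius"])
        else:
            ang = stripe["angle"]
            half = 0.5 * stripe["length"] * np.array([np.sin(ang), np.cos(ang)])
            pts = np.stack([pos - half, pos, pos + half])
            m = _polyline_mask(s, pts, max(1.0, 0.4 * stripe["radius"]))
        img[m & lobes] = config.hu_tissue

    if with_noise and config.noise_sigma > 0:
        rng = noise_rng if noise_rng is not None else np.random.default_rng(0)
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(img, config.hu_air, config.hu_tissue + 50.0)


def generate_case(config: PhantomConfig, case_seed: int) -> CaseSeries:
    """Generate one fully reproducible synthetic case stack.

    The per-case RNG is seeded from ``(config.seed, case_seed)`` so cases
    are independent of each other and of ``n_cases``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, int(case_seed))))
    geom = _case_geometry(config, rng)
    noise_rng = np.random.default_rng(np.random.SeedSequence((config.seed, int(case_seed), 1)))
    slices = [render_slice(config, geom, i, noise_rng=noise_rng)
              for i in range(config.n_slices)]
    return CaseSeries(case_id=f"case{int(case_seed):04d}", slices=slices)


def generate_dataset(config: PhantomConfig) -> List[CaseSeries]:
    """Generate ``config.n_cases`` independent cases."""
    config.validate()
    return [generate_case(config, case_seed=i) for i in range(config.n_cases)]


def lobe_region_mask(config: PhantomConfig, case_seed: int, index: int) -> np.ndarray:
    """Ground-truth lobe mask for a generated slice (for tests and oracles)."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, int(case_seed))))
    geom = _case_geometry(config, rng)
    s = config.image_size
    thorax = _disc_mask(s, (s / 2.0, s / 2.0), geom["thorax_radius"])
    a, b = geom["base_axes"]
    scale = geom["profile"][index]
    lobes = np.zeros((s, s), dtype=bool)
    for lc in lobe_centers(s):
        lobes |= _ellipse_mask(s, lc, (a * scale, b * scale)) & thorax
    return lobes
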