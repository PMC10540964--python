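"""Weak-label training-pair construction.

Two pair families feed the two similarity networks:

* contour pairs — positives are a slice and a slight thin-plate-spline
  deformation of itself (label 1); negatives are two slices of the same
  case taken from well-separated levels of the stack, where the lung
  outline has changed substantially (label 0). Balanced 1:1.

* detail pairs — positives are adjacent layers of a case (r, r±1), whose
  internal vessel/nodule content must be nearly identical (label 1);
  negatives are contour-similar but non-adjacent (or cross-case) slice
  pairs found with the already-trained contour scorer, assumed to differ
  in detail (label 0). The final similar:dissimilar ratio is enforced
  exactly (default 3:1), biasing the detail network toward similarity.

No human labels are involved anywhere: the geometry of a CT stack and the
contour scorer do all the labelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, List, Sequence, Tuple

import numpy as np

from .phantom import CaseSeries
from .stl import ControlTensor, stl_warp

logger = logging.getLogger(__name__)

Provenance = Tuple[str, int, str, int]  # (case_id, layer, case_id, layer)


class ValidationError(ValueError):
    pass


@dataclass
class PairSample:
    """Two stacked same-shape slices with a weak binary label."""

    pair: np.ndarray            # (2, H, W)
    label: int                  # 1 similar, 0 dissimilar
    pair_type: str              # "contour" | "detail"
    provenance: Provenance

    def __post_init__(self) -> None:
        self.pair = np.asarray(self.pair, dtype=float)
        if self.pair.ndim != 3 or self.pair.shape[0] != 2:
            raise ValidationError(f"pair must be (2, H, W), got {self.pair.shape}")
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")
        if self.pair_type not in ("contour", "detail"):
            raise ValidationError(f"unknown pair_type {self.pair_type!r}")


def _stack(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.stack([np.asarray(a, float), np.asarray(b, float)], axis=0)


def make_contour_pairs(cases: Sequence[CaseSeries], n_pairs: int,
                       warp_magnitude: float = 0.05, negative_gap: float = 0.3,
                       seed: int = 0, noise_sigma: float = 10.0) -> List[PairSample]:
    """Build a 1:1-balanced contour training set.

    Positives are two independently warped renditions of one slice
    (label 1); negatives are two layers of one case separated by at
    least ``negative_gap`` of the stack height (label 0). Every channel
    of every pair — positive and negative alike — goes through the same
    light spatial-transform augmentation (an independent control tensor
    of ``warp_magnitude`` plus fresh Gaussian noise of ``noise_sigma``
    HU). Applying the warp symmetrically is essential: if only the
    positive's second channel were warped, interpolation artifacts and
    the shared noise field would be perfectly label-correlated and the
    network would learn to detect warping instead of outline shape.
    Cases too short for the gap are skipped with a warning.
    """
    if not (0.0 < negative_gap <= 1.0):
        raise ValidationError("negative_gap must be in (0, 1]")
    if n_pairs < 2:
        raise ValidationError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)

    usable, skipped = [], []
    for case in cases:
        min_gap = max(1, math.ceil(negative_gap * case.n_slices))
        if case.n_slices < 3 or case.n_slices <= min_gap:
            skipped.append(case.case_id)
        else:
            usable.append((case, min_gap))
    if skipped:
        logger.warning("skipping cases too short for negative_gap=%.2f: %s",
                       negative_gap, skipped)
    if not usable:
        raise ValidationError("no case is long enough for the requested negative gap")

    def augment(sl: np.ndarray) -> np.ndarray:
        if warp_magnitude > 0:
            theta = ControlTensor(rng.uniform(-warp_magnitude, warp_magnitude,
                                              (25, 2)))
            sl = stl_warp(sl, theta)
        if noise_sigma > 0:
            sl = sl + rng.normal(0.0, noise_sigma, sl.shape)
        return sl

    n_pos = n_pairs // 2
    n_neg = n_pairs - n_pos
    out: List[PairSample] = []
    for _ in range(n_pos):
        case, _ = usable[rng.integers(len(usable))]
        r = int(rng.integers(case.n_slices))
        out.append(PairSample(
            _stack(augment(case.slices[r]), augment(case.slices[r])), 1,
            "contour", (case.case_id, r, case.case_id, r)))
    for _ in range(n_neg):
        case, min_gap = usable[rng.integers(len(usable))]
        r = int(rng.integers(case.n_slices - min_gap))
        r2 = int(rng.integers(r + min_gap, case.n_slices))
        out.append(PairSample(
            _stack(augment(case.slices[r]), augment(case.slices[r2])), 0,
            "contour", (case.case_id, r, case.case_id, r2)))
    return out


def exact_ratio_counts(n_pairs: int, ratio: Fraction | float | int) -> Tuple[int, int]:
    """Largest (n_pos, n_neg) with n_pos:n_neg exactly `ratio` and total <= n_pairs."""
    frac = Fraction(ratio).limit_denominator(1000)
    unit = frac.numerator + frac.denominator
    k = n_pairs // unit
    if k < 1:
        raise ValidationError(
            f"n_pairs={n_pairs} too small for an exact {frac.numerator}:{frac.denominator} ratio")
    return k * frac.numerator, k * frac.denominator


def make_detail_pairs(cases: Sequence[CaseSeries],
                      cs_scorer: Callable[[np.ndarray, np.ndarray], float],
                      n_pairs: int, cs_threshold: float = 0.8,
                      ratio_sim_to_dissim: Fraction | float | int = 3,
                      seed: int = 0,
                      scoring_cases: Sequence[CaseSeries] | None = None,
                      max_candidate_draws: int = 2000) -> List[PairSample]:
    """Build the detail training set at an exact similar:dissimilar ratio.

    ``cs_scorer`` maps two slices to a contour similarity in [0, 1];
    negatives must score above ``cs_threshold``. If the candidate budget
    is exhausted before enough negatives are found, the threshold is
    relaxed in 0.05 steps with a warning. ``scoring_cases`` lets the
    scorer see a different rendition of each slice (e.g. raw slices)
    than the one stacked into the pair (e.g. parenchyma-masked slices);
    it must parallel ``cases`` in layout.
    """
    if not (0.0 <= cs_threshold <= 1.0):
        raise ValidationError("cs_threshold must be in [0, 1]")
    if any(c.n_slices < 2 for c in cases):
        raise ValidationError("every case needs at least 2 slices")
    scoring = list(scoring_cases) if scoring_cases is not None else list(cases)
    if len(scoring) != len(cases) or any(a.n_slices != b.n_slices
                                         for a, b in zip(scoring, cases)):
        raise ValidationError("scoring_cases must parallel cases")

    rng = np.random.default_rng(seed)
    n_pos, n_neg = exact_ratio_counts(n_pairs, ratio_sim_to_dissim)

    out: List[PairSample] = []
    for _ in range(n_pos):
        ci = int(rng.integers(len(cases)))
        case = cases[ci]
        r = int(rng.integers(case.n_slices - 1))
        r2 = r + 1
        if rng.random() < 0.5:
            r, r2 = r2, r
        out.append(PairSample(_stack(case.slices[r], case.slices[r2]), 1, "detail",
                              (case.case_id, r, case.case_id, r2)))

    threshold = cs_threshold
    negatives: List[PairSample] = []
    draws = 0
    while len(negatives) < n_neg:
        if draws >= max_candidate_draws:
            threshold = max(0.0, threshold - 0.05)
            draws = 0
            logger.warning("not enough contour-similar negatives; relaxing "
                           "cs_threshold to %.2f", threshold)
        ci = int(rng.integers(len(cases)))
        cj = int(rng.integers(len(cases)))
        r = int(rng.integers(cases[ci].n_slices))
        r2 = int(rng.integers(cases[cj].n_slices))
        draws += 1
        if ci == cj and abs(r - r2) <= 1:
            continue  # adjacent or identical layers are detail-similar by rule
        score = float(cs_scorer(scoring[ci].slices[r], scoring[cj].slices[r2]))
        if score > threshold or threshold == 0.0:
            negatives.append(PairSample(
                _stack(cases[ci].slices[r], cases[cj].slices[r2]), 0, "detail",
                (cases[ci].case_id, r, cases[cj].case_id, r2)))
    out.extend(negatives)
    return out


def pairs_to_arrays(pairs: Sequence[PairSample]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack pairs into (N, 2, H, W) inputs and (N,) labels for training."""
    x = np.stack([p.pair for p in pairs], axis=0)
    y = np.array([p.label for p in pairs], dtype=float)
    return x, y


def save_pairs(path, pairs: Sequence[PairSample]) -> None:
    x, y = pairs_to_arrays(pairs)
    np.savez_compressed(
        path, pairs=x, labels=y,
        pair_type=np.array([p.pair_type for p in pairs]),
        provenance=np.array([list(map(str, p.provenance)) for p in pairs]))


def load_pairs(path) -> List[PairSample]:
    with np.load(path, allow_pickle=False) as z:
        return [PairSample(z["pairs"][i], int(z["labels"][i]), str(z["pair_type"][i]),
                           (z["provenance"][i][0], int(z["provenance"][i][1]),
                            z["provenance"][i][2], int(z["provenance"][i][3])))
                for i in range(len(z["labels"]))]
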