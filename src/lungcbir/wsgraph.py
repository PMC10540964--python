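"""White-stripe graph model of the pathological target area (PTA).

The bright structures inside the lung field — vessels, bronchi, nodules —
show up as "white stripes" after binarization. Each stripe is a pixel
graph: vertices are the bright pixels, and two vertices are joined when
their Euclidean distance does not exceed the adjacency radius (default 2,
which admits offsets of length 1, sqrt(2) and 2). Connected components
are grown by breadth-first search; a whole slice's stripe collection is
its PTA.

Two stripes are similar when their vertex counts agree within a relative
tolerance and their translation-invariant shape descriptors are close.
Two PTAs are similar (``b_similar``) when the number of cross-matching
stripe pairs reaches a threshold fraction of the first PTA's stripe
count — the comparison is deliberately asymmetric in the first argument,
with a symmetric variant available.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import FrozenSet, List, Tuple

import numpy as np
from skimage.measure import moments_central, moments_hu, moments_normalized

logger = logging.getLogger(__name__)

DEFAULT_WS_THRESHOLD_HU = -300.0
DEFAULT_ADJACENCY_RADIUS = 2.0
DEFAULT_COUNT_TOL = 0.25
DEFAULT_SHAPE_TOL = 0.5
DEFAULT_THETA_SIM = 0.5
N_SHAPE_FEATURES = 4


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class WhiteStripe:
    """One connected bright structure, as a pixel graph with a descriptor."""

    vertices: FrozenSet[Tuple[int, int]]
    edges: FrozenSet[Tuple[Tuple[int, int], Tuple[int, int]]]
    descriptor: np.ndarray = field(compare=False)

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> Tuple[float, float]:
        arr = np.array(sorted(self.vertices), dtype=float)
        return tuple(arr.mean(axis=0))


@dataclass
class PTA:
    """A slice's pathological target area: its list of white stripes."""

    stripes: List[WhiteStripe]
    source_shape: Tuple[int, int]

    def __len__(self) -> int:
        return len(self.stripes)

    @property
    def total_vertices(self) -> int:
        return sum(ws.vertex_count for ws in self.stripes)


def neighbor_offsets(radius: float) -> List[Tuple[int, int]]:
    """All integer offsets (dr, dc) != (0, 0) with Euclidean length <= radius."""
    r = int(np.floor(radius))
    offs = [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)
            if (dr, dc) != (0, 0) and dr * dr + dc * dc <= radius * radius]
    return offs


def shape_descriptor(vertices: np.ndarray) -> np.ndarray:
    """Translation-invariant shape features of a pixel set.

    First four Hu invariants of the binary mask of the pixels, log-scaled
    as -sign(h)*log10(|h|) so blobs of very different scales remain
    comparable on one axis.
    """
    pts = np.asarray(vertices, dtype=int)
    rmin, cmin = pts.min(axis=0)
    local = pts - [rmin, cmin]
    mask = np.zeros(local.max(axis=0) + 1, dtype=float)
    mask[local[:, 0], local[:, 1]] = 1.0
    mu = moments_central(mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = moments_normalized(mu)
    hu = moments_hu(np.nan_to_num(nu))[:N_SHAPE_FEATURES]
    return -np.sign(hu) * np.log10(np.abs(hu) + 1e-30)


def extract_pta(masked_slice: np.ndarray,
                ws_threshold_hu: float = DEFAULT_WS_THRESHOLD_HU,
                adjacency_radius: float = DEFAULT_ADJACENCY_RADIUS) -> PTA:
    """Binarize the bright structures and grow one stripe per connected
    component by breadth-first search over the adjacency offsets."""
    arr = np.asarray(masked_slice, dtype=float)
    bright = arr > ws_threshold_hu
    offs = neighbor_offsets(adjacency_radius)
    h, w = bright.shape

    remaining = {(int(r), int(c)) for r, c in zip(*np.nonzero(bright))}
    stripes: List[WhiteStripe] = []
    while remaining:
        start = min(remaining)          # deterministic seed order
        comp = {start}
        queue = deque([start])
        remaining.discard(start)
        while queue:
            r, c = queue.popleft()
            for dr, dc in offs:
                nb = (r + dr, c + dc)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        edges = set()
        for (r, c) in comp:
            for dr, dc in offs:
                nb = (r + dr, c + dc)
                if nb in comp:
                    edges.add(tuple(sorted(((r, c), nb))))
        verts = np.array(sorted(comp), dtype=int)
        stripes.append(WhiteStripe(frozenset(comp), frozenset(edges),
                                   shape_descriptor(verts)))
    return PTA(stripes=stripes, source_shape=(h, w))


def ws_similar(a: WhiteStripe, b: WhiteStripe,
               count_tol: float = DEFAULT_COUNT_TOL,
               shape_tol: float = DEFAULT_SHAPE_TOL) -> int:
    """1 iff the vertex counts agree within count_tol (relative to the
    larger) and the shape descriptors are within shape_tol (Euclidean)."""
    if a.vertex_count == 0 or b.vertex_count == 0:
        raise ValidationError("stripes must be non-empty")
    count_gate = (abs(a.vertex_count - b.vertex_count)
                  / max(a.vertex_count, b.vertex_count)) <= count_tol
    shape_gate = float(np.linalg.norm(a.descriptor - b.descriptor)) <= shape_tol
    return int(count_gate and shape_gate)


def match_sum(pta1: PTA, pta2: PTA, count_tol: float = DEFAULT_COUNT_TOL,
              shape_tol: float = DEFAULT_SHAPE_TOL) -> int:
    """The double sum of pairwise stripe similarities (with multiplicity:
    one stripe matching several counts several times)."""
    return sum(ws_similar(a, b, count_tol, shape_tol)
               for a in pta1.stripes for b in pta2.stripes)


def b_similar(pta1: PTA, pta2: PTA, theta_sim: float = DEFAULT_THETA_SIM,
              count_tol: float = DEFAULT_COUNT_TOL,
              shape_tol: float = DEFAULT_SHAPE_TOL,
              symmetric: bool = False) -> bool:
    """PTA-level detail similarity: TRUE iff the stripe match sum reaches
    theta_sim * |PTA1| (or theta_sim * min(|PTA1|, |PTA2|) in the
    symmetric variant)."""
    if theta_sim < 0:
        raise ValidationError("theta_sim must be >= 0")
    size = min(len(pta1), len(pta2)) if symmetric else len(pta1)
    if len(pta1) == 0:
        logger.debug("b_similar called with an empty first PTA (degenerate TRUE)")
    return match_sum(pta1, pta2, count_tol, shape_tol) >= theta_sim * size


def pta_to_dict(pta: PTA) -> dict:
    """JSON-serializable form of a PTA."""
    return {
        "source_shape": list(pta.source_shape),
        "stripes": [{
            "vertices": sorted(map(list, ws.vertices)),
            "edges": sorted([list(map(list, e)) for e in ws.edges]),
            "descriptor": ws.descriptor.tolist(),
        } for ws in pta.stripes],
    }


def pta_from_dict(d: dict) -> PTA:
    stripes = [WhiteStripe(
        frozenset(map(tuple, s["vertices"])),
        frozenset(tuple(map(tuple, e)) for e in s["edges"]),
        np.asarray(s["descriptor"], dtype=float)) for s in d["stripes"]]
    return PTA(stripes=stripes, source_shape=tuple(d["source_shape"]))
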