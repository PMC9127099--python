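"""Channel-difference threshold labels (CDTL) and their generalisation (GCDT).

The core idea: in many field images the foreground (vegetation) has a higher
normalized green intensity than red, while soil background has R >= G.  A
binary map obtained by thresholding G' - R' at some alpha, intersected with
the hand-drawn rough label (MGRL), yields an automatic coarse label whose
*interior* is pixel-accurate even though the MGRL is not:

    P  = [ normalized(G) - normalized(R) >= alpha ]
    P' = P & C                                   (C = MGRL region)

Channels are normalized by their per-image maximum, so thresholds are
relative intensities in [0, 1].

GCDT removes the hand-picked channel pair and alpha: for every class in the
MGRL it rates every ordered channel pair x every alpha on a grid by the IOU
between the candidate (restricted to the class's MGRL region) and a "base"
mask — the deep interior of the MGRL region obtained by cutting its
normalized Euclidean distance transform at 0.7 — and keeps the best
candidate.  The distance transform is normalized per connected component, so
the 0.7 cut is a relative depth and every blob contributes a seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CHANNELS",
    "ORDERED_PAIRS",
    "DEFAULT_ALPHA_GRID",
    "GCDTSelection",
    "normalize_channel",
    "channel_diff",
    "threshold_diff",
    "mask_with_mgrl",
    "make_cdtl",
    "distance_base",
    "score_candidate",
    "gcdt",
    "denoise_mask",
]

CHANNELS = {"R": 0, "G": 1, "B": 2}

#: the six ordered channel pairs; sign matters, so (G, R) and (R, G) are distinct
ORDERED_PAIRS: tuple[tuple[str, str], ...] = tuple(
    p for p in itertools.permutations("RGB", 2)
)

#: default alpha grid, 0.02 .. 0.50 step 0.02
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.02, 0.50 + 1e-9, 0.02), 4)
)


def _check_channel(channel: str) -> int:
    try:
        return CHANNELS[channel.upper()]
    except KeyError:
        raise ValueError(f"unknown channel {channel!r}; expected one of R, G, B") from None


def normalize_channel(image: np.ndarray, channel: str) -> np.ndarray:
    """Channel divided by its per-image maximum, as float64 in [0, 1].

    An identically-zero channel maps to all zeros (documented convention).
    """
    idx = _check_channel(channel)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    chan = image[..., idx].astype(np.float64)
    m = chan.max()
    if m == 0:
        return np.zeros_like(chan)
    return chan / m


def channel_diff(image: np.ndarray, pair: tuple[str, str]) -> np.ndarray:
    """Signed difference normalized(first) - normalized(second), in [-1, 1]."""
    first, second = pair
    if first.upper() == second.upper():
        raise ValueError("channel pair must use two distinct channels")
    return normalize_channel(image, first) - normalize_channel(image, second)


def threshold_diff(diff: np.ndarray, alpha: float) -> np.ndarray:
    """Binary map: 1 where diff >= alpha (ties count as foreground)."""
    return (np.asarray(diff) >= alpha).astype(np.uint8)


def mask_with_mgrl(p: np.ndarray, mgrl_region: np.ndarray) -> np.ndarray:
    """Pixel-wise AND of a threshold map with an MGRL class region."""
    p = np.asarray(p)
    mgrl_region = np.asarray(mgrl_region)
    if p.shape != mgrl_region.shape:
        raise ValueError(
            f"shape mismatch: threshold map {p.shape} vs MGRL region {mgrl_region.shape}"
        )
    return ((p > 0) & (mgrl_region > 0)).astype(np.uint8)


def distance_base(mgrl: np.ndarray, class_id: int, cut: float = 0.7) -> np.ndarray:
    """Binary "base" mask: deep interior of a class's MGRL region.

    Euclidean distance to the region boundary is computed inside the class
    region, normalized by the maximum within each connected component, and
    binarized at ``cut``.  Every nonempty component therefore keeps at least
    its deepest pixel; an isolated pixel is its own base.
    """
    region = np.asarray(mgrl) == class_id
    base = np.zeros(region.shape, dtype=np.uint8)
    if not region.any():
        warnings.warn(f"class {class_id} absent from MGRL; empty base", stacklevel=2)
        return base
    dist = ndimage.distance_transform_edt(region)
    labels, n = ndimage.label(region)
    for comp in range(1, n + 1):
        sel = labels == comp
        m = dist[sel].max()
        base[sel] = (dist[sel] / m) >= cut
    return base


def score_candidate(candidate: np.ndarray, base: np.ndarray) -> float:
    """IOU between a candidate threshold label and the base mask.

    Both empty -> 0.0: an empty candidate carries no evidence that it matches
    the class interior, so it never wins the selection.
    """
    candidate = np.asarray(candidate) > 0
    base = np.asarray(base) > 0
    if candidate.shape != base.shape:
        raise ValueError("candidate and base shapes differ")
    union = np.count_nonzero(candidate | base)
    if union == 0:
        return 0.0
    return np.count_nonzero(candidate & base) / union


@dataclass(frozen=True)
class GCDTSelection:
    """Winning candidate for one class: channel pair, alpha and its IOU score."""

    class_id: int
    pair: tuple[str, str]
    alpha: float
    score: float
    fallback: bool = False  # True when all candidates were empty and the base was used

    def to_dict(self) -> dict:
        return {
            "class_id": self.class_id,
            "pair": "-".join(self.pair).lower(),
            "alpha": self.alpha,
            "score": self.score,
            "fallback": self.fallback,
        }


def _select_for_class(
    image: np.ndarray,
    region: np.ndarray,
    class_id: int,
    alpha_grid,
    pairs,
    cut: float,
) -> tuple[np.ndarray, GCDTSelection]:
    base = distance_base(region.astype(np.uint8), 1, cut=cut)
    best = (-1.0, None, None, None)  # score, pair, alpha, mask
    for pair in pairs:
        diff = channel_diff(image, pair)
        for alpha in alpha_grid:
            cand = mask_with_mgrl(threshold_diff(diff, alpha), region)
            s = score_candidate(cand, base)
            if s > best[0]:
                best = (s, pair, float(alpha), cand)
    score, pair, alpha, mask = best
    if mask is None or not mask.any():
        warnings.warn(
            f"all GCDT candidates empty for class {class_id}; falling back to the base",
            stacklevel=3,
        )
        return base, GCDTSelection(class_id, pairs[0], float(alpha_grid[0]), 0.0, True)
    return mask, GCDTSelection(class_id, pair, alpha, score)


def gcdt(
    image: np.ndarray,
    mgrl: np.ndarray,
    alpha_grid=DEFAULT_ALPHA_GRID,
    pairs=ORDERED_PAIRS,
    cut: float = 0.7,
) -> tuple[np.ndarray, list[GCDTSelection]]:
    """Generalized channel-difference thresholding over all MGRL classes.

    Returns a label mask (0 = background, class indices as in the MGRL) and
    the per-class selections.  A pixel claimed by several classes goes to the
    class with the higher selection score; ties go to the lower class index.
    """
    mgrl = np.asarray(mgrl)
    classes = sorted(int(k) for k in np.unique(mgrl) if k != 0)
    if not classes:
        raise ValueError("MGRL contains no foreground classes")
    masks: dict[int, np.ndarray] = {}
    selections: list[GCDTSelection] = []
    for k in classes:
        mask, sel = _select_for_class(
            image, (mgrl == k).astype(np.uint8), k, alpha_grid, pairs, cut
        )
        masks[k] = mask
        selections.append(sel)

    out = np.zeros(mgrl.shape, dtype=np.uint8)
    # paint in descending score so higher-score classes win overlaps;
    # equal scores painted in descending class index so the lower index wins
    order = sorted(selections, key=lambda s: (s.score, -s.class_id))
    for sel in order:
        out[masks[sel.class_id] > 0] = sel.class_id
    return out, selections


def make_cdtl(
    image: np.ndarray,
    mgrl: np.ndarray,
    pair: tuple[str, str] = ("G", "R"),
    alpha: float | str = 0.1,
    alpha_grid=DEFAULT_ALPHA_GRID,
    cut: float = 0.7,
) -> tuple[np.ndarray, GCDTSelection]:
    """Plain single-class CDTL: normalize -> diff -> threshold -> AND MGRL.

    ``alpha='auto'`` reuses the GCDT base-IOU scoring restricted to the given
    pair, so the same selection principle backs both paths.
    """
    mgrl = np.asarray(mgrl)
    classes = [int(k) for k in np.unique(mgrl) if k != 0]
    if len(classes) > 1:
        raise ValueError(
            "make_cdtl handles a single foreground class; use gcdt() for "
            f"multi-class MGRLs (found classes {classes})"
        )
    if not classes:
        empty = np.zeros(mgrl.shape, dtype=np.uint8)
        a = float(alpha) if alpha != "auto" else float(alpha_grid[0])
        return empty, GCDTSelection(0, pair, a, 0.0)
    k = classes[0]
    region = (mgrl == k).astype(np.uint8)
    if alpha == "auto":
        mask, sel = _select_for_class(image, region, k, alpha_grid, (pair,), cut)
        return mask, sel
    diff = channel_diff(image, pair)
    mask = mask_with_mgrl(threshold_diff(diff, float(alpha)), region)
    base = distance_base(region, 1, cut=cut)
    return mask, GCDTSelection(k, pair, float(alpha), score_candidate(mask, base))


def denoise_mask(mask: np.ndarray, kind: str = "median", window: int = 3) -> np.ndarray:
    """Noise filtering of a binary mask (optional post-processing).

    ``average``: box filter then re-binarize at 0.5 (>= 0.5 -> foreground);
    ``median``: median filter.  Edges are handled by nearest-value padding.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    mask = (np.asarray(mask) > 0).astype(np.float64)
    if kind == "average":
        sm = ndimage.uniform_filter(mask, size=window, mode="nearest")
        # uniform_filter accumulates in floating point; snap values that are
        # within rounding error of 0.5 so the tie rule is exact
        sm = np.where(np.isclose(sm, 0.5), 0.5, sm)
        return (sm >= 0.5).astype(np.uint8)
    if kind == "median":
        return ndimage.median_filter(mask, size=window, mode="nearest").astype(np.uint8)
    raise ValueError(f"unknown filter kind {kind!r}; expected 'average' or 'median'")
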