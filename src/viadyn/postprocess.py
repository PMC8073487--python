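"""From a pixel probability map to lesion regions and a sequence call.

Steps: neutralize specular reflections to 0.5, multiply by a radial
distance map (1 at the center, 0.5 at the farthest point — precancer
favors the central cervix), grow regions from up to five seeds under a
dual homogeneity / minimum-probability predicate, close each region with
a 7x7 kernel, and call the sequence positive if any region reaches the
size threshold (450 px at the working resolution).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from skimage import measure

from .config import PipelineConfig


@dataclass
class ProbabilityMap:
    """H x W CIN2+ probabilities plus the reflection mask."""

    probs: np.ndarray
    reflection_mask: np.ndarray
    patient_id: str = ""
    model_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.reflection_mask = np.asarray(self.reflection_mask, dtype=bool)
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.reflection_mask.shape != self.probs.shape:
            raise ValueError("reflection mask must match the probability grid")


@dataclass
class DistanceMap:
    """Radial weights: 1 at the center, 0.5 at the farthest grid point."""

    weights: np.ndarray
    center: tuple


@dataclass
class LesionPrediction:
    """Labeled lesion regions and the binary sequence decision."""

    region_labels: np.ndarray
    region_sizes: dict
    contours: dict
    decision: str  # "positive" | "negative"
    size_threshold_used: int


def neutralize_reflections(pmap: ProbabilityMap) -> ProbabilityMap:
    """Set flagged pixels to the neutral 0.5; all others untouched."""
    probs = pmap.probs.copy()
    probs[pmap.reflection_mask] = 0.5
    return ProbabilityMap(probs, pmap.reflection_mask.copy(),
                          pmap.patient_id, pmap.model_id)


def make_distance_map(shape: tuple, center: tuple | None = None) -> DistanceMap:
    """weight(p) = 1 - 0.5 * dist(p, center) / max_dist (linear decay)."""
    H, W = shape
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    cy, cx = center
    if not (0 <= cy <= H - 1 and 0 <= cx <= W - 1):
        raise ValueError(f"center {center} outside grid {shape}")
    yy, xx = np.mgrid[:H, :W]
    dist = np.hypot(yy - cy, xx - cx)
    max_dist = dist.max()
    if max_dist == 0:
        return DistanceMap(np.ones(shape), center)
    return DistanceMap(1.0 - 0.5 * dist / max_dist, center)


def modulate(pmap: ProbabilityMap, dmap: DistanceMap) -> ProbabilityMap:
    """Element-wise product of probabilities and distance weights."""
    if dmap.weights.shape != pmap.probs.shape:
        raise ValueError("distance map must match the probability grid")
    return ProbabilityMap(pmap.probs * dmap.weights, pmap.reflection_mask.copy(),
                          pmap.patient_id, pmap.model_id)


def _grow_from(probs: np.ndarray, seed: tuple, in_region: np.ndarray,
               homogeneity_thr: float, min_prob: float,
               anchor: str) -> np.ndarray:
    """BFS over 4-neighbors; a pixel joins iff |anchor_prob - p| <
    homogeneity_thr and p > min_prob. ``anchor`` is 'seed' (all
    comparisons against the originating seed) or 'parent'."""
    H, W = probs.shape
    region = np.zeros_like(in_region)
    region[seed] = True
    queue = deque([seed])
    seed_prob = probs[seed]
    while queue:
        r, c = queue.popleft()
        ref_prob = seed_prob if anchor == "seed" else probs[r, c]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < H and 0 <= nc < W):
                continue
            if region[nr, nc] or in_region[nr, nc]:
                continue
            p = probs[nr, nc]
            if abs(ref_prob - p) < homogeneity_thr and p > min_prob:
                region[nr, nc] = True
                queue.append((nr, nc))
    return region


def region_growing(
    pmap: ProbabilityMap | np.ndarray,
    n_seeds: int = 5,
    homogeneity_thr: float = 0.27,
    min_prob: float = 0.50,
    rng_seed=0,
    seed_top_fraction: float = 0.005,
    anchor: str = "seed",
) -> np.ndarray:
    """Seeded region growing on a probability map; returns a label grid.

    The first seed is drawn uniformly from the top ``seed_top_fraction``
    of probabilities; each later seed is the highest-probability pixel
    not yet in any region. A seed below ``min_prob`` cannot start a
    region (every remaining pixel is lower still), so seeding stops.
    """
    probs = pmap.probs if isinstance(pmap, ProbabilityMap) else np.asarray(pmap, float)
    if not (0 <= homogeneity_thr <= 1 and 0 <= min_prob <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if anchor not in ("seed", "parent"):
        raise ValueError("anchor must be 'seed' or 'parent'")
    rng = np.random.default_rng(rng_seed)
    H, W = probs.shape
    labels = np.zeros((H, W), dtype=int)
    in_region = np.zeros((H, W), dtype=bool)
    next_label = 1
    for k in range(n_seeds):
        if k == 0:
            cutoff = np.quantile(probs, 1.0 - seed_top_fraction)
            cand = np.argwhere(probs >= cutoff)
            seed = tuple(cand[rng.integers(len(cand))])
            if in_region[seed]:  # cannot happen on the first seed, kept for safety
                continue
        else:
            masked = np.where(in_region, -np.inf, probs)
            flat = int(np.argmax(masked))
            seed = (flat // W, flat % W)
        if probs[seed] <= min_prob:
            break
        region = _grow_from(probs, seed, in_region, homogeneity_thr, min_prob, anchor)
        in_region |= region
        labels[region] = next_label
        next_label += 1
    return labels


def close_regions(labels: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Per-region morphological closing with a square kernel.

    Closing is dilation followed by erosion with the same kernel,
    computed as on the infinite plane (the grid is padded by the kernel
    radius so border regions are not clipped; closing stays extensive).
    Region identity is preserved; closing only claims pixels that are
    background in the current label grid (earlier regions keep theirs).
    """
    out = labels.copy()
    structure = np.ones((kernel, kernel), bool)
    r = kernel // 2
    for lab in sorted(np.unique(labels)):
        if lab == 0:
            continue
        padded = np.pad(labels == lab, r, constant_values=False)
        dilated = binary_dilation(padded, structure, border_value=0)
        closed = binary_erosion(dilated, structure, border_value=0)
        closed = closed[r:-r, r:-r] if r else closed
        out[closed & (out == 0)] = lab
    return out


def decide_sequence(labels: np.ndarray,
                    size_threshold: int = 450) -> LesionPrediction:
    """Positive iff any region's pixel count reaches the size threshold."""
    region_ids = [int(v) for v in np.unique(labels) if v != 0]
    sizes = {lab: int((labels == lab).sum()) for lab in region_ids}
    contours = {}
    for lab in region_ids:
        mask = (labels == lab).astype(float)
        contours[lab] = measure.find_contours(mask, 0.5)
    decision = "positive" if any(s >= size_threshold for s in sizes.values()) \
        else "negative"
    return LesionPrediction(region_labels=labels, region_sizes=sizes,
                            contours=contours, decision=decision,
                            size_threshold_used=int(size_threshold))


def postprocess_map(pmap: ProbabilityMap, config: PipelineConfig | None = None,
                    rng_seed=0, center: tuple | None = None) -> LesionPrediction:
    """Full postprocessing chain: neutralize, modulate, grow, close, decide."""
    config = config or PipelineConfig()
    neutral = neutralize_reflections(pmap)
    dmap = make_distance_map(neutral.probs.shape, center)
    modulated = modulate(neutral, dmap)
    labels = region_growing(
        modulated, n_seeds=config.n_seeds,
        homogeneity_thr=config.homogeneity_threshold,
        min_prob=config.min_probability, rng_seed=rng_seed,
        seed_top_fraction=config.seed_top_fraction,
        anchor=config.homogeneity_anchor)
    closed = close_regions(labels, config.closing_kernel)
    return decide_sequence(closed, config.size_threshold)
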