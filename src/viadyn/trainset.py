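"""Supervised pixel selection from colposcopist annotation masks.

Annotations drawn on the last frame are imprecise near lesion borders
and smeared by residual motion, so training pixels keep away from them:
positives are sampled inside the eroded label, negatives inside a
central cervix mask minus the dilated label, with a band along the image
borders removed. Reflection and out-of-view pixels are excluded, and the
positive class is augmented by curve scaling to balance the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk, erosion


@dataclass
class AnnotationMask:
    """Binary lesion annotation in last-frame coordinates."""

    mask: np.ndarray
    patient_id: str = ""
    annotator_id: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SamplingRegions:
    """Disjoint candidate regions for positive and negative pixels."""

    positive_region: np.ndarray
    negative_region: np.ndarray
    disk_radius_erode: int
    disk_radius_dilate: int

    def __post_init__(self):
        if np.any(self.positive_region & self.negative_region):
            raise ValueError("sampling regions must be disjoint")


def central_disc_mask(image_size: int, radius_frac: float = 0.45) -> np.ndarray:
    """Default central mask: a disc covering the middle of the frame,
    keeping negative samples away from regions far from the cervix center."""
    s = image_size
    yy, xx = np.mgrid[:s, :s]
    c = (s - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= (radius_frac * s) ** 2


def choose_disk_radius(mask: AnnotationMask | np.ndarray,
                       override: int | None = None) -> tuple:
    """Structuring-element radius from the lesion's equivalent diameter.

    Default rule: 10% of the equivalent diameter 2*sqrt(area/pi), clipped
    to [2, 12] px; used for both erosion and dilation. A manual override
    wins (the study set the size by hand per lesion).
    """
    if override is not None:
        return int(override), int(override)
    arr = mask.mask if isinstance(mask, AnnotationMask) else np.asarray(mask, bool)
    area = int(arr.sum())
    if area == 0:
        raise ValueError("cannot choose a disk radius for an empty mask")
    eq_diameter = 2.0 * np.sqrt(area / np.pi)
    r = int(np.clip(round(0.1 * eq_diameter), 2, 12))
    return r, r


def build_sampling_regions(
    mask: AnnotationMask | np.ndarray,
    erode_r: int,
    dilate_r: int,
    central_mask: np.ndarray,
    border_margin: int = 5,
) -> SamplingRegions:
    """Erode the label for positives; dilate + centrally mask for negatives.

    The annulus between the eroded and dilated label is in neither region,
    and a ``border_margin`` band along every image edge is removed from
    the negative region.
    """
    arr = mask.mask if isinstance(mask, AnnotationMask) else np.asarray(mask, bool)
    if erode_r < 1 or dilate_r < 1:
        raise ValueError("structuring-element radii must be >= 1")
    if central_mask.shape != arr.shape:
        raise ValueError("central mask must match the annotation shape")
    if arr.any():
        positive = erosion(arr, disk(erode_r))
        if not positive.any():
            raise ValueError(
                f"erosion with radius {erode_r} empties the label; "
                "use a smaller radius")
        dilated = dilation(arr, disk(dilate_r))
    else:
        positive = arr.copy()
        dilated = arr.copy()
    negative = central_mask & ~dilated
    if border_margin > 0:
        border = np.zeros_like(negative)
        m = border_margin
        border[:m, :] = border[-m:, :] = True
        border[:, :m] = border[:, -m:] = True
        negative &= ~border
    return SamplingRegions(positive, negative, erode_r, dilate_r)


def sample_pixels(
    regions: SamplingRegions,
    reflection_mask: np.ndarray | None,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator | int,
    valid_mask: np.ndarray | None = None,
) -> tuple:
    """Uniformly sample (row, col) pixels without replacement per region,
    excluding reflection and invalid pixels. Reproducible under a seed."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    exclude = np.zeros_like(regions.positive_region)
    if reflection_mask is not None:
        exclude |= np.asarray(reflection_mask, bool)
    if valid_mask is not None:
        exclude |= ~np.asarray(valid_mask, bool)

    out = []
    for region, n in ((regions.positive_region, n_pos),
                      (regions.negative_region, n_neg)):
        candidates = np.argwhere(region & ~exclude)
        if n > len(candidates):
            raise ValueError(
                f"requested {n} pixels but only {len(candidates)} available "
                "after exclusions")
        idx = rng.choice(len(candidates), size=n, replace=False) if n else []
        out.append(candidates[np.asarray(idx, dtype=int)])
    return out[0], out[1]


def augment_positive(
    features: np.ndarray,
    target_count: int,
    rng: np.random.Generator | int,
    scale_range: tuple = (0.9, 1.15),
) -> np.ndarray:
    """Grow the positive set to ``target_count`` by scaling whole curves.

    Each synthesized sample is an existing curve multiplied by one scalar
    drawn uniformly from ``scale_range`` — the same factor at every time
    point.
    """
    features = np.asarray(features, dtype=float)
    n = len(features)
    if n == 0:
        raise ValueError("cannot augment an empty feature set")
    if target_count < n:
        raise ValueError(f"target_count {target_count} below current count {n}")
    if target_count == n:
        return features.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sources = rng.integers(0, n, size=target_count - n)
    factors = rng.uniform(scale_range[0], scale_range[1], size=target_count - n)
    synthesized = features[sources] * factors[:, None]
    return np.concatenate([features, synthesized], axis=0)
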