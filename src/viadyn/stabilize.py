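"""Camera-motion compensation by point-feature matching.

Every frame is registered to a reference frame (by default the last one,
which is where lesion annotations are drawn): Harris corners are
detected on a lightly smoothed grayscale, described with BRIEF, matched
brute-force with cross-checking, and a similarity transform is fitted by
RANSAC. Because the expected motion is a small camera wobble, matches
whose displacement strays far from the median displacement are trimmed
before the consensus fit — this removes most outliers up front and lets
RANSAC terminate quickly. Degenerate frames (too few features or
matches) fall back to the identity transform with a flag rather than
failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2gray
from skimage.feature import BRIEF, corner_harris, corner_peaks, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform, warp

from .io import VideoSequence

MIN_MATCHES = 6
#: Harris response floor — rejects sensor-noise ripples while keeping
#: genuine tissue-texture corners (absolute, not relative, so saturated
#: specular highlights cannot crowd everything else out).
HARRIS_THRESHOLD = 3e-7
#: BRIEF sampling pattern seed; must be identical for every frame.
_BRIEF_SEED = 42
#: Matches farther than this (px) from the median displacement are
#: trimmed before the consensus fit.
DISPLACEMENT_TRIM = 3.0


@dataclass
class FrameTransform:
    """Similarity transform mapping a moving frame into reference coordinates."""

    frame_index: int
    transform: SimilarityTransform
    n_inliers: int
    fallback_used: bool

    @property
    def translation(self) -> np.ndarray:
        """(dx, dy) of the estimated transform, in pixels."""
        return np.asarray(self.transform.translation)


def _frame_features(frame: np.ndarray, n_keypoints: int):
    """Harris corners + BRIEF descriptors on smoothed grayscale."""
    gray = gaussian_filter(rgb2gray(frame), 1.0)
    corners = corner_peaks(corner_harris(gray), min_distance=3,
                           threshold_rel=None, threshold_abs=HARRIS_THRESHOLD,
                           num_peaks=n_keypoints)
    if len(corners) < MIN_MATCHES:
        return None, None
    extractor = BRIEF(patch_size=25, rng=_BRIEF_SEED)
    extractor.extract(gray, corners)
    keypoints = corners[extractor.mask]
    if len(keypoints) < MIN_MATCHES:
        return None, None
    return keypoints, extractor.descriptors


def estimate_frame_transform(
    reference: np.ndarray,
    moving: np.ndarray,
    frame_index: int = 0,
    n_keypoints: int = 300,
    _ref_features=None,
) -> FrameTransform:
    """Estimate the similarity transform taking ``moving`` onto ``reference``.

    ``_ref_features`` optionally carries precomputed reference keypoints
    and descriptors so sequence stabilization extracts them only once.
    """
    if reference.shape != moving.shape:
        raise ValueError("frames must share a shape")
    identity = FrameTransform(frame_index, SimilarityTransform(), 0, True)
    if _ref_features is None:
        _ref_features = _frame_features(reference, n_keypoints)
    ref_kp, ref_desc = _ref_features
    if ref_kp is None:
        warnings.warn("reference frame has too few features; identity fallback")
        return identity
    mov_kp, mov_desc = _frame_features(moving, n_keypoints)
    if mov_kp is None:
        warnings.warn(f"frame {frame_index}: too few features; identity fallback")
        return identity
    matches = match_descriptors(ref_desc, mov_desc, cross_check=True)
    if len(matches) < MIN_MATCHES:
        warnings.warn(f"frame {frame_index}: too few matches; identity fallback")
        return identity
    # keypoints are (row, col); transforms work in (x, y)
    dst = ref_kp[matches[:, 0]][:, ::-1].astype(float)
    src = mov_kp[matches[:, 1]][:, ::-1].astype(float)
    # small-wobble prior: trim matches far from the median displacement
    displacement = dst - src
    median_disp = np.median(displacement, axis=0)
    keep = np.linalg.norm(displacement - median_disp, axis=1) < DISPLACEMENT_TRIM
    if keep.sum() >= 3:
        src, dst = src[keep], dst[keep]
    try:
        model, inliers = ransac(
            (src, dst), SimilarityTransform, min_samples=3,
            residual_threshold=0.75, max_trials=100,
            stop_probability=0.9999, rng=0,
        )
    except Exception:
        model, inliers = None, None
    if model is None or inliers is None or inliers.sum() < 3 or not np.all(
            np.isfinite(model.params)):
        warnings.warn(f"frame {frame_index}: consensus fit failed; identity fallback")
        return identity
    return FrameTransform(frame_index, model, int(inliers.sum()), False)


def stabilize_sequence(
    seq: VideoSequence,
    reference_index: int | None = None,
    n_keypoints: int = 300,
) -> tuple:
    """Warp every frame into the reference frame's coordinates.

    Returns the stabilized sequence (with ``valid_mask`` marking pixels
    that stayed in view in all frames) and the per-frame transforms.
    """
    if reference_index is None:
        reference_index = seq.n_frames - 1
    if not (0 <= reference_index < seq.n_frames):
        raise ValueError(f"reference_index {reference_index} out of range")
    reference = seq.frames[reference_index]
    ref_features = _frame_features(reference, n_keypoints)

    transforms = []
    out = np.empty_like(seq.frames)
    valid = np.ones(seq.shape, dtype=bool)
    for i, frame in enumerate(seq.frames):
        if i == reference_index:
            ft = FrameTransform(i, SimilarityTransform(), 0, False)
            out[i] = frame
            transforms.append(ft)
            continue
        ft = estimate_frame_transform(reference, frame, frame_index=i,
                                      n_keypoints=n_keypoints,
                                      _ref_features=ref_features)
        transforms.append(ft)
        if ft.fallback_used:
            out[i] = frame
            continue
        warped = warp(frame.astype(float), ft.transform.inverse, order=1,
                      mode="constant", cval=np.nan, preserve_range=True)
        bad = np.any(~np.isfinite(warped), axis=-1)
        valid &= ~bad
        warped[bad] = 0.0
        out[i] = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    stabilized = VideoSequence(out, seq.timestamps.copy(), seq.patient_id,
                               valid_mask=valid)
    return stabilized, transforms


def transforms_to_table(transforms: list) -> "list[dict]":
    """Per-frame transform parameters, ready for a CSV dump."""
    rows = []
    for ft in transforms:
        dx, dy = ft.translation
        rows.append({
            "frame": ft.frame_index, "dx": dx, "dy": dy,
            "rotation": ft.transform.rotation, "scale": ft.transform.scale,
            "inliers": ft.n_inliers, "fallback": ft.fallback_used,
        })
    return rows
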