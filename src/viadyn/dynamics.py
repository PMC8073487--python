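"""Per-pixel temporal features from a stabilized RGB stack.

The chain is: scale channels to [-0.5, 0.5], project each pixel's RGB
onto the whitening principal axis (one scalar per pixel per frame),
discard the first frames (most affected by movement), and downsample
each pixel's curve to a fixed number of time points with a natural cubic
spline. Specular reflections are flagged wherever the projected scalar's
temporal maximum exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .config import DEFAULT_PRINCIPAL_AXIS
from .io import VideoSequence


@dataclass
class PrincipalAxis:
    """Unit direction in scaled-RGB space along which tissue whitens."""

    direction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("principal axis must be a 3-vector")
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero axis")
        self.direction = d / n


def default_axis() -> PrincipalAxis:
    """The stored training-set mean axis, renormalized to unit length."""
    return PrincipalAxis(np.asarray(DEFAULT_PRINCIPAL_AXIS))


@dataclass
class ScalarSequence:
    """T x H x W grid of projected intensities plus the axis used."""

    values: np.ndarray
    axis_used: np.ndarray
    valid_mask: np.ndarray | None = None
    timestamps: np.ndarray | None = None
    patient_id: str = ""


@dataclass
class PixelFeature:
    """One pixel's downsampled intensity curve — the classifier input."""

    curve: np.ndarray
    pixel: tuple
    patient_id: str = ""

    def __post_init__(self):
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 1:
            raise ValueError("curve must be 1-D")


def scale_channels(frames: np.ndarray) -> np.ndarray:
    """Map 8-bit channel values to [-0.5, 0.5] via v/255 - 0.5."""
    arr = np.asarray(frames, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return arr / 255.0 - 0.5


def estimate_principal_axis(samples: np.ndarray) -> PrincipalAxis:
    """First principal direction of scaled-RGB samples (N x 3).

    The sign is fixed so the axis points along the whitening direction
    (positive component sum); zero-variance input is rejected.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3 or len(samples) < 2:
        raise ValueError("need at least two RGB samples")
    centered = samples - samples.mean(axis=0)
    cov = centered.T @ centered / (len(samples) - 1)
    if not np.any(np.abs(cov) > 1e-15):
        raise ValueError("samples have zero variance; no principal axis exists")
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]
    if axis.sum() < 0:
        axis = -axis
    return PrincipalAxis(axis)


def mean_axis(axes: list) -> PrincipalAxis:
    """Component-wise mean of unit axes, renormalized."""
    if not axes:
        return default_axis()
    stack = np.stack([a.direction for a in axes])
    return PrincipalAxis(stack.mean(axis=0))


def project_sequence(scaled: np.ndarray, axis: PrincipalAxis | None = None,
                     valid_mask: np.ndarray | None = None,
                     timestamps: np.ndarray | None = None,
                     patient_id: str = "") -> ScalarSequence:
    """Dot each scaled RGB pixel with the axis: (T,H,W,3) -> (T,H,W)."""
    if axis is None:
        axis = default_axis()
    values = np.tensordot(np.asarray(scaled, float), axis.direction, axes=([-1], [0]))
    return ScalarSequence(values=values, axis_used=axis.direction,
                          valid_mask=valid_mask, timestamps=timestamps,
                          patient_id=patient_id)


def project_video(seq: VideoSequence, axis: PrincipalAxis | None = None) -> ScalarSequence:
    """Convenience: scale an 8-bit sequence and project it."""
    return project_sequence(scale_channels(seq.frames), axis,
                            valid_mask=seq.valid_mask,
                            timestamps=seq.timestamps,
                            patient_id=seq.patient_id)


def extract_curve(scalar_seq: ScalarSequence, pixel: tuple,
                  discard_first: int = 10) -> np.ndarray:
    """One pixel's projected curve with the first frames dropped."""
    T = scalar_seq.values.shape[0]
    if T <= discard_first:
        raise ValueError(f"sequence of {T} frames cannot discard {discard_first}")
    r, c = pixel
    return scalar_seq.values[discard_first:, r, c].copy()


def downsample_curve(raw: np.ndarray, n_out: int = 11) -> np.ndarray:
    """Natural cubic spline through the raw curve, evaluated at ``n_out``
    equally spaced abscissae spanning [0, L-1] inclusive."""
    raw = np.asarray(raw, dtype=float)
    L = raw.shape[0]
    if L < 4:
        raise ValueError(f"cubic spline downsampling needs >= 4 points, got {L}")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    spline = CubicSpline(np.arange(L), raw, axis=0, bc_type="natural")
    return spline(np.linspace(0.0, L - 1.0, n_out))


def compute_features(scalar_seq: ScalarSequence, discard_first: int = 10,
                     n_out: int = 11) -> np.ndarray:
    """All pixels' downsampled curves at once: returns (H, W, n_out)."""
    vals = scalar_seq.values[discard_first:]
    L, H, W = vals.shape
    flat = vals.reshape(L, H * W)
    feats = downsample_curve(flat, n_out)  # (n_out, H*W)
    return np.moveaxis(feats, 0, -1).reshape(H, W, n_out)


def detect_reflections(scalar_seq: ScalarSequence,
                       threshold: float = 0.25) -> np.ndarray:
    """Flag pixels whose projected scalar ever (strictly) exceeds the
    threshold — specular highlights saturate the whitening axis."""
    return scalar_seq.values.max(axis=0) > threshold
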