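"""Phantom VIA videos with known ground truth.

Real acetowhitening recordings show two temporal signatures: CIN2+ tissue
whitens quickly after acetic acid is applied and then fades smoothly,
while benign epithelium stays nearly constant. The phantom renders an
elliptical cervix disc with mild multiplicative texture on a dark
background, drives lesion pixels with a single-peak whitening pulse and
the rest of the disc with a slow drift, then adds static specular
highlights, per-frame global jitter, and sensor noise. Whitening is
applied as an additive RGB shift along the scaled-RGB principal axis, so
the projection stage downstream recovers the designed scalar curve.

All randomness flows from one seed; identical seeds give bit-identical
phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .config import DEFAULT_PRINCIPAL_AXIS
from .io import VideoSequence, save_frames, save_mask

#: Cervix base color (RGB, 8-bit) — a muted pink chosen so its projection
#: onto the whitening axis sits well below the specular threshold.
CERVIX_COLOR = np.array([168.0, 108.0, 98.0])
BACKGROUND_COLOR = np.array([18.0, 12.0, 12.0])

_UNIT_AXIS = np.asarray(DEFAULT_PRINCIPAL_AXIS) / np.linalg.norm(DEFAULT_PRINCIPAL_AXIS)


@dataclass
class PhantomSpec:
    """Parameters of one phantom recording.

    ``kinetics_pos`` is (amplitude A, rise time t_peak [s], decay constant
    tau [s]) of the lesion whitening pulse, in projected-scalar units;
    ``kinetics_neg`` is (baseline offset, drift amplitude) for benign
    tissue. ``noise_sigma`` is in 8-bit channel units, ``jitter_sigma`` in
    pixels.
    """

    image_size: int = 150
    n_frames: int = 120
    fps: float = 1.0
    lesion_masks: list = field(default_factory=list)
    kinetics_pos: tuple = (0.16, 25.0, 60.0)
    kinetics_neg: tuple = (0.03, 0.02)
    reflection_count: int = 4
    jitter_sigma: float = 1.2
    noise_sigma: float = 2.5
    texture_amplitude: float = 0.10
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_frames < 12:
            raise ValueError("n_frames must be >= 12")
        A, t_peak, tau = self.kinetics_pos
        if not (0 < A <= 1):
            raise ValueError("whitening amplitude A must be in (0, 1]")
        if t_peak <= 0 or tau <= 0:
            raise ValueError("t_peak and tau must be positive")
        for m in self.lesion_masks:
            m = np.asarray(m)
            if m.shape != (self.image_size, self.image_size):
                raise ValueError("lesion masks must match image_size")

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.fps


@dataclass
class PhantomTruth:
    """Ground truth of a phantom: what the pipeline should recover."""

    lesion_mask: np.ndarray
    per_frame_shift: np.ndarray  # (T, 2) integer (dy, dx)
    reflection_mask: np.ndarray
    patient_label: str  # "positive" | "negative"
    cervix_mask: np.ndarray | None = None

    def __post_init__(self):
        has_lesion = bool(np.any(self.lesion_mask))
        if has_lesion != (self.patient_label == "positive"):
            raise ValueError("patient_label must be positive iff a lesion exists")


def acetowhitening_curve(t, tissue: str, spec: PhantomSpec) -> np.ndarray:
    """Designed whitening intensity (projected-scalar units) at time ``t``.

    Positive tissue follows a gamma-like pulse
    ``baseline + A * ((t/t_peak) * exp(1 - t/t_peak)) ** (t_peak/tau)``:
    a single maximum of height ``baseline + A`` at ``t_peak`` and an
    asymptotic exponential decay with time constant ``tau``. Negative
    tissue stays within ``drift`` of its baseline (a slow half-period
    sinusoidal drift over the recording).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    baseline = spec.kinetics_neg[0]
    if tissue == "positive":
        A, t_peak, tau = spec.kinetics_pos
        x = t / t_peak
        pulse = np.where(x > 0, (x * np.exp(1.0 - x)) ** (t_peak / tau), 0.0)
        return baseline + A * pulse
    if tissue == "negative":
        drift = spec.kinetics_neg[1]
        return baseline + drift * np.sin(np.pi * t / max(spec.duration, 1e-9) / 2.0)
    raise ValueError(f"unknown tissue class {tissue!r}")


def elliptical_cervix_mask(image_size: int, rx_frac: float = 0.44,
                           ry_frac: float = 0.40) -> np.ndarray:
    s = image_size
    yy, xx = np.mgrid[:s, :s]
    cy = cx = (s - 1) / 2.0
    return ((yy - cy) / (ry_frac * s)) ** 2 + ((xx - cx) / (rx_frac * s)) ** 2 <= 1.0


def random_lesion_mask(image_size: int, rng: np.random.Generator,
                       semi_axis_range: tuple = (16.0, 24.0),
                       max_center_offset: float = 25.0) -> np.ndarray:
    """A random rotated ellipse near the cervix center (lesion footprint)."""
    s = image_size
    cy = (s - 1) / 2.0 + rng.uniform(-max_center_offset, max_center_offset)
    cx = (s - 1) / 2.0 + rng.uniform(-max_center_offset, max_center_offset)
    a = rng.uniform(*semi_axis_range)
    b = rng.uniform(*semi_axis_range)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[:s, :s]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _reflection_field(spec: PhantomSpec, cervix: np.ndarray,
                      rng: np.random.Generator) -> tuple:
    """Static specular highlights: Gaussian blobs clipped at saturation."""
    s = spec.image_size
    intensity = np.zeros((s, s))
    mask = np.zeros((s, s), dtype=bool)
    if spec.reflection_count <= 0:
        return intensity, mask
    inside = np.argwhere(cervix)
    sigma = 1.8
    for _ in range(spec.reflection_count):
        cy, cx = inside[rng.integers(len(inside))]
        yy, xx = np.mgrid[:s, :s]
        r2 = (yy - cy) ** 2.0 + (xx - cx) ** 2.0
        blob = 600.0 * np.exp(-r2 / (2 * sigma**2))
        intensity = np.maximum(intensity, blob)
        mask |= blob > 200.0
    return intensity, mask


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render a phantom recording and its ground truth.

    Per-frame global integer shifts are drawn from N(0, jitter_sigma) and
    recorded in the truth; the last frame's shift is forced to (0, 0) so
    truth masks (annotated in last-frame coordinates, as in the
    acquisition protocol) coincide with the stabilization reference.
    """
    rng = np.random.default_rng(spec.rng_seed)
    s = spec.image_size
    cervix = elliptical_cervix_mask(s)
    lesion = np.zeros((s, s), dtype=bool)
    for m in spec.lesion_masks:
        m = np.asarray(m, dtype=bool)
        if np.any(m & ~cervix):
            raise ValueError("lesion mask exceeds the cervix disc")
        lesion |= m
    label = "positive" if lesion.any() else "negative"

    # static tissue texture: coarse mottling plus fine speckle
    # (multiplicative; fine scale gives the stabilizer corners to track)
    coarse = gaussian_filter(rng.standard_normal((s, s)), sigma=2.0)
    fine = gaussian_filter(rng.standard_normal((s, s)), sigma=0.8)
    coarse /= max(np.abs(coarse).max(), 1e-12)
    fine /= max(np.abs(fine).max(), 1e-12)
    texture = spec.texture_amplitude * (0.6 * coarse + 0.4 * fine)

    base = np.where(cervix[..., None], CERVIX_COLOR * (1.0 + texture)[..., None],
                    BACKGROUND_COLOR)
    refl_intensity, refl_mask = _reflection_field(spec, cervix, rng)

    t = np.arange(spec.n_frames) / spec.fps
    pos_curve = acetowhitening_curve(t, "positive", spec)
    neg_curve = acetowhitening_curve(t, "negative", spec)

    shifts = np.rint(rng.normal(0.0, spec.jitter_sigma, size=(spec.n_frames, 2))
                     ).astype(int) if spec.jitter_sigma > 0 else np.zeros(
                         (spec.n_frames, 2), dtype=int)
    shifts[-1] = 0

    frames = np.empty((spec.n_frames, s, s, 3), dtype=np.uint8)
    for i in range(spec.n_frames):
        scalar = np.where(lesion, pos_curve[i], np.where(cervix, neg_curve[i], 0.0))
        frame = base + scalar[..., None] * 255.0 * _UNIT_AXIS
        frame = np.maximum(frame, refl_intensity[..., None])
        if np.any(shifts[i] != 0):
            dy, dx = shifts[i]
            frame = np.stack(
                [nd_shift(frame[..., c], (dy, dx), order=0, mode="constant",
                          cval=BACKGROUND_COLOR[c]) for c in range(3)], axis=-1)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    truth = PhantomTruth(lesion_mask=lesion, per_frame_shift=shifts,
                         reflection_mask=refl_mask, patient_label=label,
                         cervix_mask=cervix)
    seq = VideoSequence(frames=frames, timestamps=t, patient_id=f"phantom-{spec.rng_seed}")
    return seq, truth


def generate_cohort(n_positive: int, n_negative: int, seed: int,
                    **spec_overrides) -> list:
    """A list of (spec, VideoSequence, PhantomTruth), positives first.

    Patient seeds are derived deterministically from ``seed``; positive
    patients get 1–2 random elliptical lesions.
    """
    master = np.random.default_rng(seed)
    cohort = []
    for k in range(n_positive + n_negative):
        patient_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(patient_seed)
        size = spec_overrides.get("image_size", 150)
        if k < n_positive:
            n_lesions = int(rng.integers(1, 3))
            masks = [random_lesion_mask(size, rng) for _ in range(n_lesions)]
        else:
            masks = []
        spec = PhantomSpec(lesion_masks=masks, rng_seed=patient_seed,
                           **spec_overrides)
        seq, truth = generate_phantom(spec)
        seq.patient_id = f"P{k:03d}"
        cohort.append((spec, seq, truth))
    return cohort


def write_phantom(directory: str | Path, seq: VideoSequence,
                  truth: PhantomTruth) -> None:
    """Write frames as numbered PNGs plus a JSON truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_frames(seq, directory)
    save_mask(truth.lesion_mask, directory / "lesion_mask.png")
    save_mask(truth.reflection_mask, directory / "reflection_mask.png")
    sidecar = {
        "patient_id": seq.patient_id,
        "patient_label": truth.patient_label,
        "lesion_mask": "lesion_mask.png",
        "reflection_mask": "reflection_mask.png",
        "per_frame_shift": truth.per_frame_shift.tolist(),
    }
    (directory / "truth.json").write_text(json.dumps(sidecar, indent=2))
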