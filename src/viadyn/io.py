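"""Video, mask, and manifest I/O.

A recording is either a standard video container or a directory of
numbered frame images. Frames are resampled to the working frame rate by
nearest-timestamp selection, cropped with a fixed box (the same box for
every frame, so anatomy stays registered) and resized to the square
working resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

FRAME_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


@dataclass
class VideoSequence:
    """Ordered stack of RGB frames with timestamps and a patient id.

    ``frames`` is a (T, H, W, 3) uint8 array with channel values in
    [0, 255]; ``timestamps`` are seconds, strictly increasing.
    ``valid_mask`` (optional, set by stabilization) marks pixels that stay
    in view across all frames.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    patient_id: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        if len(self.frames) < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames disagree in length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:3]


@dataclass
class ManifestEntry:
    patient_id: str
    video: Path
    label: str  # "positive" | "negative"
    masks: list = field(default_factory=list)  # annotation masks, ordered by annotator


@dataclass
class Manifest:
    entries: list

    def __post_init__(self):
        ids = [e.patient_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids in a manifest must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def _list_frame_files(directory: Path) -> list:
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in FRAME_EXTENSIONS and not p.name.startswith(".")
    )
    # directories may hold sidecar masks next to the frames; when files
    # follow the frame_NNN naming, only those are the video
    frame_named = [p for p in files if p.stem.startswith("frame")]
    return frame_named or files


def load_sequence(
    path: str | Path,
    target_fps: float | None = 1.0,
    native_fps: float = 1.0,
    patient_id: str | None = None,
) -> VideoSequence:
    """Load a video container or a frame directory and resample to ``target_fps``.

    Frame directories are read in lexicographic order of their zero-padded
    names and assumed to tick at ``native_fps``. Resampling picks, for each
    tick of the target clock, the frame with the nearest source timestamp.
    """
    path = Path(path)
    if path.is_dir():
        files = _list_frame_files(path)
        if not files:
            raise IOError(f"no frame images found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
        if frames.ndim == 3:  # grayscale stack
            frames = np.repeat(frames[..., None], 3, axis=-1)
        if frames.shape[-1] == 4:
            frames = frames[..., :3]
        timestamps = np.arange(len(frames)) / native_fps
    else:
        if not path.exists():
            raise IOError(f"no such video: {path}")
        try:
            frames = np.asarray(iio.imread(path, plugin="pyav"))
        except Exception:
            try:
                frames = np.asarray(iio.imread(path))
            except Exception as exc:  # unreadable container
                raise IOError(f"cannot read video container {path}: {exc}") from exc
        if frames.ndim == 3:
            frames = frames[None] if frames.shape[-1] == 3 else np.repeat(frames[..., None], 3, -1)
        try:
            meta = iio.immeta(path)
            native_fps = float(meta.get("fps", native_fps))
        except Exception:
            pass
        timestamps = np.arange(len(frames)) / native_fps

    if target_fps is not None and target_fps > 0:
        duration = timestamps[-1]
        n_ticks = int(np.floor(duration * target_fps + 1e-9)) + 1
        grid = np.arange(n_ticks) / target_fps
        picks = np.abs(timestamps[None, :] - grid[:, None]).argmin(axis=1)
        frames = frames[picks]
        timestamps = grid
    if len(frames) < 2:
        raise ValueError(f"fewer than 2 frames after sampling ({len(frames)})")
    return VideoSequence(
        frames=frames.astype(np.uint8),
        timestamps=timestamps,
        patient_id=patient_id or path.stem,
    )


def centered_square(shape: tuple) -> tuple:
    """Largest centered square crop box (row0, col0, height, width)."""
    h, w = shape[:2]
    side = min(h, w)
    return ((h - side) // 2, (w - side) // 2, side, side)


def crop_and_resize(
    seq: VideoSequence,
    crop_box: tuple | None = None,
    out_size: int = 150,
) -> VideoSequence:
    """Apply one crop box to every frame and resize to ``out_size`` square.

    ``crop_box`` is (row0, col0, height, width); ``None`` uses the largest
    centered square. Bilinear interpolation; output stays uint8.
    """
    h, w = seq.shape
    if crop_box is None:
        crop_box = centered_square((h, w))
    r0, c0, ch, cw = crop_box
    if r0 < 0 or c0 < 0 or ch <= 0 or cw <= 0 or r0 + ch > h or c0 + cw > w:
        raise ValueError(f"crop box {crop_box} outside frame bounds {(h, w)}")
    cropped = seq.frames[:, r0 : r0 + ch, c0 : c0 + cw]
    if (ch, cw) == (out_size, out_size):
        out = cropped.copy()
    else:
        out = np.empty((seq.n_frames, out_size, out_size, 3), dtype=np.uint8)
        for i, frame in enumerate(cropped):
            res = resize(frame.astype(float), (out_size, out_size), order=1,
                         anti_aliasing=False, preserve_range=True)
            out[i] = np.clip(np.rint(res), 0, 255).astype(np.uint8)
    return VideoSequence(out, seq.timestamps.copy(), seq.patient_id)


def save_frames(seq: VideoSequence, directory: str | Path) -> list:
    """Write frames as zero-padded PNGs (lossless); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    width = max(3, len(str(seq.n_frames - 1)))
    for i, frame in enumerate(seq.frames):
        p = directory / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from a single-channel PNG (any nonzero = lesion)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def save_probability_map(probs: np.ndarray, path_prefix: str | Path) -> None:
    """Write a probability grid as a 16-bit PNG plus exact values (.npy)."""
    path_prefix = Path(path_prefix)
    png = (np.clip(probs, 0, 1) * 65535).astype(np.uint16)
    iio.imwrite(path_prefix.with_suffix(".png"), png)
    np.save(path_prefix.with_suffix(".npy"), np.asarray(probs, dtype=np.float64))


def load_probability_map(path_prefix: str | Path) -> np.ndarray:
    return np.load(Path(path_prefix).with_suffix(".npy"))


def read_manifest(path: str | Path) -> Manifest:
    """Read a CSV or JSON manifest (patient_id, video, label, mask...)."""
    path = Path(path)
    root = path.parent
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        records = df.to_dict("records")
    entries = []
    for rec in records:
        label = str(rec["label"]).strip().lower()
        if label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {rec['label']!r}")
        raw_masks = rec.get("mask") or rec.get("masks") or ""
        if isinstance(raw_masks, float) and np.isnan(raw_masks):
            raw_masks = ""
        if isinstance(raw_masks, str):
            mask_paths = [m for m in raw_masks.split(";") if m]
        else:
            mask_paths = list(raw_masks)
        video = root / str(rec["video"])
        if not video.exists():
            raise IOError(f"manifest references missing video {video}")
        masks = []
        for m in mask_paths:
            mp = root / m
            if not mp.exists():
                raise IOError(f"manifest references missing mask {mp}")
            masks.append(mp)
        entries.append(ManifestEntry(str(rec["patient_id"]), video, label, masks))
    return Manifest(entries)
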