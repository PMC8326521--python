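"""Video / image-sequence input and the pixel-to-micrometer scale calibration.

The imaging geometry is a microfluidic channel observed from above; the chip
embeds scale markers of known physical length, so the calibration is a single
scalar delta (micrometers per pixel) measured from a marker's length in pixels.

Coordinates are 0-based with ``x`` = column and ``y`` = row, origin at the
top-left of the frame; flow runs along +x (the channel's long axis).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameSequence",
    "ScaleCalibration",
    "calibrate_scale",
    "read_frame",
    "read_sequence",
    "write_sequence",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov"}


@dataclass
class FrameSequence:
    """Ordered 8-bit RGB frames plus acquisition metadata.

    ``frame_rate`` is metadata only: no time-based physics is computed, and
    frame-to-frame displacement is handled by the tracking cost directly.
    """

    frames: list[np.ndarray] = field(default_factory=list)
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed dimensions: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __getitem__(self, index: int) -> np.ndarray:
        return self.frames[index]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of the frames."""
        if not self.frames:
            raise ValueError("empty FrameSequence has no frame shape")
        return self.frames[0].shape[:2]


@dataclass(frozen=True)
class ScaleCalibration:
    """Micrometers-per-pixel conversion, delta = marker_um / marker_px."""

    delta_um_per_px: float
    marker_length_px: float | None = None
    marker_length_um: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_um_per_px) or self.delta_um_per_px <= 0:
            raise ValueError(
                f"delta_um_per_px must be positive, got {self.delta_um_per_px}"
            )

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.delta_um_per_px

    def area_px_to_um2(self, area_px: float) -> float:
        return area_px * self.delta_um_per_px**2


def calibrate_scale(marker_length_px: float, marker_length_um: float) -> ScaleCalibration:
    """Derive delta from a scale marker of known physical length.

    Parameters
    ----------
    marker_length_px : float
        Measured length of the marker in pixels (e.g. 460 px for the 1 mm
        marker at the reference magnification).
    marker_length_um : float
        Physical length of the marker in micrometers.
    """
    if marker_length_px <= 0 or marker_length_um <= 0:
        raise ValueError(
            "marker lengths must be positive, got "
            f"{marker_length_px} px / {marker_length_um} um"
        )
    return ScaleCalibration(
        delta_um_per_px=marker_length_um / marker_length_px,
        marker_length_px=marker_length_px,
        marker_length_um=marker_length_um,
    )


def _to_rgb8(img: np.ndarray) -> np.ndarray:
    """Coerce a decoded image to 8-bit RGB (HxWx3 uint8)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(arr, 0.0, 1.0) * 255.0
        elif arr.dtype == np.uint16:
            arr = arr / 257.0
        arr = np.round(arr).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"cannot interpret image of shape {np.asarray(img).shape} as RGB")
    return arr


def _numeric_sort_key(path: Path) -> tuple:
    """Sort frame files by the trailing integer in their stem, then by name."""
    m = re.search(r"(\d+)(?!.*\d)", path.stem)
    return (0, int(m.group(1)), path.name) if m else (1, 0, path.name)


def read_frame(path: str | Path) -> np.ndarray:
    """Read a single image file as an 8-bit RGB array."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    try:
        return _to_rgb8(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - decoding failures become I/O errors
        raise IOError(f"could not decode image {path}: {exc}") from exc


def read_sequence(path: str | Path, frame_rate: float = 30.0) -> FrameSequence:
    """Read an mp4 video or a numbered PNG/TIFF sequence into a FrameSequence.

    ``path`` may be a video file, a directory of numbered images, a glob
    pattern, or a single image file (degenerate one-frame sequence). Frames
    are returned in temporal order and decoded to 8-bit RGB. Mixed frame
    dimensions raise a format error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_numeric_sort_key,
        )
        if not files:
            raise IOError(f"no PNG/TIFF frames found in directory {path}")
        frames = [read_frame(p) for p in files]
    elif "*" in path.name:
        files = sorted(path.parent.glob(path.name), key=_numeric_sort_key)
        if not files:
            raise IOError(f"no frames match pattern {path}")
        frames = [read_frame(p) for p in files]
    elif path.suffix.lower() in _VIDEO_SUFFIXES:
        if not path.exists():
            raise IOError(f"no such video: {path}")
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:  # noqa: BLE001
            raise IOError(
                f"could not decode video {path}; an ffmpeg/pyav imageio plugin "
                f"is required for compressed video ({exc})"
            ) from exc
        frames = [_to_rgb8(f) for f in np.asarray(raw)]
    elif path.exists():
        frames = [read_frame(path)]
    else:
        raise IOError(f"no such input: {path}")

    shapes = {f.shape[:2] for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
    return FrameSequence(frames=frames, frame_rate=frame_rate)


def write_sequence(
    sequence: FrameSequence | Sequence[np.ndarray],
    directory: str | Path,
    prefix: str = "frame_",
) -> list[Path]:
    """Write frames as numbered PNGs; the written files round-trip losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = list(sequence)
    width = max(4, len(str(max(len(frames) - 1, 0))))
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}{i:0{width}d}.png"
        iio.imwrite(p, _to_rgb8(frame))
        paths.append(p)
    return paths
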