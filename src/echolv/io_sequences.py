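"""Reading and writing echo sequences, masks, contours and area curves.

Conventions used throughout the package
---------------------------------------
* Images are 2-D ``float64`` arrays with intensities in ``[0, 1]``,
  0-based indexing, row index ``y`` growing downward and column index ``x``
  growing rightward.  ``array[y, x]`` addresses the pixel at ``(x, y)``.
* Masks are 2-D ``uint8`` arrays with values in ``{0, 1}``.
* Contours are ``(N, 2)`` integer arrays of ``(x, y)`` pixel coordinates,
  ordered clockwise (in image/screen coordinates) and closed implicitly
  (last point is 8-adjacent to the first).

On disk, frames and masks are PNG/TIFF rasters, contours are two-column CSV
files with header ``x,y``, area curves are CSV with header
``frame,time_s,area_cm2`` and sequence metadata is a sidecar JSON file with
keys ``frame_rate_hz``, ``pixel_spacing_mm`` (``[dy, dx]``) and
``r_wave_indices``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "EchoSequence",
    "as_image",
    "as_mask",
    "as_contour",
    "load_sequence",
    "load_contour_csv",
    "write_contour_csv",
    "load_mask_png",
    "write_mask_png",
    "write_area_curve_csv",
    "load_area_curve_csv",
]

MIN_IMAGE_SIZE = 8

_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


def as_image(arr: np.ndarray, *, check_size: bool = False) -> np.ndarray:
    """Validate and return ``arr`` as a float64 image in [0, 1]."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError(f"image must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite values")
    if img.size and (img.min() < 0.0 or img.max() > 1.0):
        raise ValidationError("image intensities must lie in [0, 1]")
    if check_size and (img.shape[0] < MIN_IMAGE_SIZE or img.shape[1] < MIN_IMAGE_SIZE):
        raise ValidationError(
            f"image must be at least {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}, got {img.shape}"
        )
    return img


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and return ``arr`` as a uint8 binary mask."""
    mask = np.asarray(arr)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.dtype == bool:
        return mask.astype(np.uint8)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(f"mask values must be binary, found {uniq[:8]}")
    return mask.astype(np.uint8)


def as_contour(points: Sequence[Sequence[int]] | np.ndarray) -> np.ndarray:
    """Validate and return contour points as an (N, 2) int array of (x, y)."""
    pts = np.asarray(points, dtype=np.int64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValidationError(f"contour must be a non-empty (N, 2) array, got {pts.shape}")
    if pts.shape[0] > 1 and np.any(np.all(pts[1:] == pts[:-1], axis=1)):
        raise ValidationError("contour has repeated consecutive points")
    return pts


@dataclass
class EchoSequence:
    """An ordered grayscale frame sequence with timing and ECG R-wave markers.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Intensities in [0, 1]; all frames share the same dimensions.
    frame_rate : float
        Acquisition rate in Hz (nominally 44 frames/s).
    pixel_spacing : (float, float)
        ``(dy, dx)`` pixel size in mm.
    r_wave_indices : list of int
        Strictly increasing frame indices of the ECG R waves delimiting
        cardiac cycles.  Two R waves mark the starts of the two consecutive
        cycles required by the time-averaging filter.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: tuple[float, float]
    r_wave_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3 or frames.shape[0] == 0:
            raise ValidationError(
                f"frames must be a non-empty (n, H, W) stack, got shape {frames.shape}"
            )
        as_image(frames[0], check_size=True)
        if not np.all(np.isfinite(frames)):
            raise ValidationError("frames contain non-finite values")
        if frames.min() < 0.0 or frames.max() > 1.0:
            raise ValidationError("frame intensities must lie in [0, 1]")
        self.frames = frames
        if not (self.frame_rate > 0 and math.isfinite(self.frame_rate)):
            raise ValidationError(f"frame_rate must be positive, got {self.frame_rate}")
        dy, dx = self.pixel_spacing
        if not (dy > 0 and dx > 0):
            raise ValidationError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(dy), float(dx))
        r = [int(i) for i in self.r_wave_indices]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValidationError(f"r_wave_indices must be strictly increasing, got {r}")
        if r and (r[0] < 0 or r[-1] >= self.n_frames):
            raise ValidationError(
                f"r_wave_indices {r} out of range for {self.n_frames} frames"
            )
        self.r_wave_indices = r

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def frame(self, k: int) -> np.ndarray:
        return self.frames[k]

    def require_two_cycles(self) -> None:
        if len(self.r_wave_indices) < 2:
            raise ValidationError(
                "two-cycle processing requires at least two R-wave indices, "
                f"got {self.r_wave_indices}"
            )

    def cycle_bounds(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Frame ranges [start, stop) of the first two cardiac cycles."""
        self.require_two_cycles()
        r = self.r_wave_indices
        stop2 = r[2] if len(r) > 2 else self.n_frames
        return (r[0], r[1]), (r[1], stop2)


def _rescale_raster(raw: np.ndarray) -> np.ndarray:
    """Map integer rasters onto [0, 1] by full-range division."""
    if raw.ndim == 3:  # collapse RGB(A) gray frames
        raw = raw[..., 0]
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    img = raw.astype(np.float64)
    if img.size and img.max() > 1.0:
        raise FormatError(f"cannot rescale raster of dtype {raw.dtype} with max {img.max()}")
    return img


def _read_frame_stack(frames_path: Path) -> np.ndarray:
    if frames_path.is_dir():
        files = sorted(
            p for p in frames_path.iterdir() if p.suffix.lower() in _RASTER_SUFFIXES
        )
        if not files:
            raise FormatError(f"no PNG/TIFF frames found in {frames_path}")
        frames = [_rescale_raster(iio.imread(p)) for p in files]
    else:
        raw = iio.imread(frames_path)
        if raw.ndim == 2:
            raw = raw[None]
        frames = [_rescale_raster(fr) for fr in raw]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"frames have inconsistent shapes: {sorted(shapes)}")
    return np.stack(frames)


def load_sequence(
    frames_path: str | Path,
    metadata_path: str | Path,
    *,
    require_two_cycles: bool = True,
) -> EchoSequence:
    """Load an :class:`EchoSequence` from raster frames plus sidecar JSON.

    ``frames_path`` may be a directory of lexicographically ordered PNG/TIFF
    files or a multi-frame TIFF.  8-bit intensities are divided by 255 and
    16-bit by 65535.
    """
    frames_path, metadata_path = Path(frames_path), Path(metadata_path)
    if not metadata_path.exists():
        raise ConfigurationError(f"metadata file not found: {metadata_path}")
    with open(metadata_path) as fh:
        meta = json.load(fh)
    missing = {"frame_rate_hz", "pixel_spacing_mm", "r_wave_indices"} - set(meta)
    if missing:
        raise ConfigurationError(f"metadata {metadata_path} missing keys: {sorted(missing)}")
    frames = _read_frame_stack(frames_path)
    seq = EchoSequence(
        frames=frames,
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_spacing=tuple(float(v) for v in meta["pixel_spacing_mm"]),
        r_wave_indices=list(meta["r_wave_indices"]),
    )
    if require_two_cycles:
        seq.require_two_cycles()
    return seq


def save_metadata(seq: EchoSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "frame_rate_hz": seq.frame_rate,
                "pixel_spacing_mm": list(seq.pixel_spacing),
                "r_wave_indices": seq.r_wave_indices,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_contour_csv(contour: np.ndarray, path: str | Path) -> None:
    contour = as_contour(contour)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("x", "y"))
        writer.writerows(contour.tolist())


def load_contour_csv(path: str | Path) -> np.ndarray:
    rows: list[tuple[int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"empty contour file: {path}")
        if [h.strip().lower() for h in header] != ["x", "y"]:
            raise FormatError(f"contour CSV must have header 'x,y', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                x, y = (int(v) for v in row)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed contour row {row}") from exc
            rows.append((x, y))
    if not rows:
        raise ValidationError(f"contour file has no points: {path}")
    return as_contour(rows)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    mask = as_mask(mask)
    iio.imwrite(Path(path), (mask * np.uint8(255)))


def load_mask_png(path: str | Path) -> np.ndarray:
    raw = iio.imread(Path(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    uniq = np.unique(raw)
    if not np.all(np.isin(uniq, (0, 255))):
        raise FormatError(f"mask PNG {path} contains non-binary values {uniq[:8]}")
    return (raw == 255).astype(np.uint8)


def write_area_curve_csv(
    frame_indices: Sequence[int],
    times: Sequence[float],
    areas: Sequence[float],
    path: str | Path,
) -> None:
    """Write an area curve as CSV; missing areas (NaN) are left blank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("frame", "time_s", "area_cm2"))
        for k, t, a in zip(frame_indices, times, areas):
            writer.writerow((int(k), repr(float(t)), "" if math.isnan(a) else repr(float(a))))


def load_area_curve_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frames, times, areas = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["frame", "time_s", "area_cm2"]:
            raise FormatError(f"area-curve CSV must have header 'frame,time_s,area_cm2'")
        for row in reader:
            if not row:
                continue
            frames.append(int(row[0]))
            times.append(float(row[1]))
            areas.append(float(row[2]) if row[2] != "" else math.nan)
    if not frames:
        raise ValidationError(f"area-curve file has no rows: {path}")
    return np.asarray(frames), np.asarray(times), np.asarray(areas)
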