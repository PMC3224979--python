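"""Area variation curve (AVC) and area variation fraction (AVF).

The AVC plots left-ventricular cavity area (cm²) against time over one
cardiac cycle; the AVF, ``100 * (A - E) / A`` with ``A`` the end-diastolic
and ``E`` the end-systolic area, summarizes global systolic function much
like the ventricular shortening fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_sequences import EchoSequence, as_mask
from .segment import SegmentationResult

__all__ = [
    "AreaCurve",
    "AVFResult",
    "frame_area",
    "build_avc",
    "detect_ed_es",
    "compute_avf",
    "avf_from_curve",
]


def frame_area(mask: np.ndarray, pixel_spacing: tuple[float, float]) -> float:
    """Cavity area in cm²: foreground pixel count × pixel area (dy·dx mm²)."""
    mask = as_mask(mask)
    dy, dx = pixel_spacing
    if not (dy > 0 and dx > 0):
        raise ValidationError(f"pixel spacing must be positive, got {pixel_spacing}")
    return int(mask.sum()) * dy * dx / 100.0


@dataclass
class AreaCurve:
    """Per-frame ventricular area over the cycle; NaN marks failed frames."""

    frame_indices: np.ndarray
    times: np.ndarray
    areas: np.ndarray
    pixel_area_cm2: float

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        if not (len(self.frame_indices) == len(self.times) == len(self.areas)):
            raise ValidationError("AreaCurve lists must have equal lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        present = self.areas[~np.isnan(self.areas)]
        if present.size and present.min() < 0:
            raise ValidationError("areas must be nonnegative")

    @property
    def n_present(self) -> int:
        return int(np.sum(~np.isnan(self.areas)))


@dataclass(frozen=True)
class AVFResult:
    """Area variation fraction with the frames and areas that define it."""

    avf: float  # percent
    ed_index: int
    es_index: int
    ed_area: float  # cm²
    es_area: float  # cm²


def build_avc(results: Sequence[SegmentationResult], seq: EchoSequence) -> AreaCurve:
    """Turn per-frame segmentation results into an area curve.

    Failed frames contribute missing (NaN) areas rather than being dropped,
    so gaps remain visible in the curve.
    """
    if not results:
        raise ValidationError("no segmentation results to build an AVC from")
    dy, dx = seq.pixel_spacing
    areas = [
        frame_area(r.corrected_mask, seq.pixel_spacing) if r.ok else math.nan
        for r in results
    ]
    if all(math.isnan(a) for a in areas):
        raise ValidationError("every frame failed; AVC undefined")
    idx = np.array([r.frame_index for r in results], dtype=np.int64)
    return AreaCurve(
        frame_indices=idx,
        times=idx / seq.frame_rate,
        areas=np.array(areas),
        pixel_area_cm2=dy * dx / 100.0,
    )


def detect_ed_es(
    avc: AreaCurve, r_wave_frame: int = 0, *, ed_at_r: bool = False
) -> tuple[int, int]:
    """Automatic end-diastole / end-systole frame selection.

    End-diastole is the first frame with a present area strictly after the R
    wave (or at the R wave with ``ed_at_r=True``); end-systole is the frame
    of lowest present area, earliest on ties.  Missing frames are skipped,
    not interpolated.
    """
    if avc.n_present < 2:
        raise ValidationError("ED/ES detection needs at least two present areas")
    frames = avc.frame_indices
    if r_wave_frame > frames.max():
        raise ValidationError(
            f"R-wave frame {r_wave_frame} beyond the area curve (last {frames.max()})"
        )
    present = ~np.isnan(avc.areas)
    after = frames >= r_wave_frame if ed_at_r else frames > r_wave_frame
    candidates = np.nonzero(after & present)[0]
    if candidates.size == 0:
        raise ValidationError(f"no present area after R-wave frame {r_wave_frame}")
    ed_pos = int(candidates[0])
    areas = np.where(present, avc.areas, np.inf)
    es_pos = int(np.argmin(areas))  # argmin returns the earliest tie
    return int(frames[ed_pos]), int(frames[es_pos])


def compute_avf(ed_area: float, es_area: float) -> float:
    """AVF = 100 × (A − E) / A, in percent."""
    if not ed_area > 0:
        raise ValidationError(f"end-diastolic area must be positive, got {ed_area}")
    if es_area < 0:
        raise ValidationError(f"end-systolic area must be nonnegative, got {es_area}")
    if es_area > ed_area:
        raise ValidationError(
            f"end-systolic area {es_area} exceeds end-diastolic area {ed_area}"
        )
    return 100.0 * (ed_area - es_area) / ed_area


def avf_from_curve(
    avc: AreaCurve, r_wave_frame: int = 0, *, ed_at_r: bool = False
) -> AVFResult:
    """Detect ED/ES on the curve and compute the AVF in one step."""
    ed_index, es_index = detect_ed_es(avc, r_wave_frame, ed_at_r=ed_at_r)
    pos = {int(f): i for i, f in enumerate(avc.frame_indices)}
    ed_area = float(avc.areas[pos[ed_index]])
    es_area = float(avc.areas[pos[es_index]])
    return AVFResult(
        avf=compute_avf(ed_area, es_area),
        ed_index=ed_index,
        es_index=es_index,
        ed_area=ed_area,
        es_area=es_area,
    )
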