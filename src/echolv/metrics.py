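"""Segmentation-agreement metrics between automatic and manual results.

Four metrics compare an automatically estimated segmentation ``A`` with a
manual reference ``M``:

* RMSd — root mean squared distance between paired contour points (pixels);
* CCC  — cross-correlation coefficient of the mean-removed binary masks;
* PE   — percent area-estimation error, ``100·| |A| − |M| | / |M|``;
* ES   — error sum, ``100·(|A ∩ M̄| + |Ā ∩ M|) / |M|`` (false positives plus
  false negatives relative to the manual area; an edge-positioning error).

Contour points are paired by index after both contours are re-rooted at
their minimal-(y, x) pixel, oriented clockwise, and the longer one is evenly
decimated to the shorter one's length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .io_sequences import as_contour, as_mask
from .segment import extract_contour

__all__ = [
    "MetricReport",
    "resample_even",
    "canonicalize_contour",
    "rmsd_contours",
    "ccc_masks",
    "percent_error",
    "error_sum",
    "evaluate_pair",
    "summarize_reports",
]


@dataclass(frozen=True)
class MetricReport:
    """The four agreement metrics for one automatic/manual pair."""

    rmsd: float  # pixels
    ccc: float  # dimensionless, in [-1, 1]
    pe: float  # percent
    es: float  # percent
    n_points: int  # common contour length used for RMSd


def resample_even(contour: np.ndarray, n: int) -> np.ndarray:
    """Evenly decimate a contour to ``n`` points.

    Keeps the points at original indices ``round(i·L/n)`` for
    ``i = 0..n-1`` (``L`` the original length), preserving order.
    """
    contour = as_contour(contour)
    length = contour.shape[0]
    if n <= 0:
        raise ValidationError(f"target length must be positive, got {n}")
    if n > length:
        raise ValidationError(f"cannot resample {length} points up to {n}")
    idx = np.rint(np.arange(n) * (length / n)).astype(np.int64)
    return contour[idx]


def _signed_area(contour: np.ndarray) -> float:
    """Shoelace sum; positive for clockwise order in image (y-down) coordinates."""
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def canonicalize_contour(contour: np.ndarray) -> np.ndarray:
    """Re-root at the minimal-(y, x) point and enforce clockwise orientation."""
    contour = as_contour(contour)
    if contour.shape[0] > 2 and _signed_area(contour) < 0:
        contour = contour[::-1]
    i0 = np.lexsort((contour[:, 0], contour[:, 1]))[0]
    return np.roll(contour, -i0, axis=0)


def rmsd_contours(auto: np.ndarray, manual: np.ndarray) -> float:
    """Root mean squared distance between index-paired contour points.

    Both contours are canonicalized (common root and orientation), the
    longer one is evenly decimated to the shorter one's length N, and the
    metric is ``sqrt((1/N) Σ ||p_i^A − p_i^M||²)``.
    """
    auto = canonicalize_contour(auto)
    manual = canonicalize_contour(manual)
    n = min(auto.shape[0], manual.shape[0])
    a = resample_even(auto, n).astype(np.float64)
    m = resample_even(manual, n).astype(np.float64)
    return float(np.sqrt(np.mean(np.sum((a - m) ** 2, axis=1))))


def ccc_masks(a: np.ndarray, m: np.ndarray) -> float:
    """Pearson correlation of the two mean-removed binary masks over all pixels."""
    a, m = as_mask(a), as_mask(m)
    if a.shape != m.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {m.shape}")
    at = a.astype(np.float64) - a.mean()
    mt = m.astype(np.float64) - m.mean()
    denom = np.sqrt(np.sum(at * at) * np.sum(mt * mt))
    if denom == 0:
        raise UndefinedMetricError("CCC undefined for a constant mask (zero variance)")
    return float(np.sum(at * mt) / denom)


def percent_error(a: np.ndarray, m: np.ndarray) -> float:
    """PE = 100 × | |A| − |M| | / |M| (absolute relative area error)."""
    a, m = as_mask(a), as_mask(m)
    na, nm = int(a.sum()), int(m.sum())
    if nm == 0:
        raise ValidationError("PE undefined for an empty manual mask")
    return 100.0 * abs(na - nm) / nm


def error_sum(a: np.ndarray, m: np.ndarray) -> float:
    """ES = 100 × (|A ∩ M̄| + |Ā ∩ M|) / |M| (symmetric-difference error)."""
    a, m = as_mask(a), as_mask(m)
    if a.shape != m.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {m.shape}")
    nm = int(m.sum())
    if nm == 0:
        raise ValidationError("ES undefined for an empty manual mask")
    fp = int(np.sum((a == 1) & (m == 0)))
    fn = int(np.sum((a == 0) & (m == 1)))
    return 100.0 * (fp + fn) / nm


def evaluate_pair(auto_mask: np.ndarray, manual_mask: np.ndarray) -> MetricReport:
    """Compute all four metrics for one automatic/manual mask pair.

    Contours for RMSd are extracted from the masks by Moore boundary
    tracing.
    """
    auto_mask, manual_mask = as_mask(auto_mask), as_mask(manual_mask)
    auto_contour = extract_contour(auto_mask)
    manual_contour = extract_contour(manual_mask)
    n = min(auto_contour.shape[0], manual_contour.shape[0])
    return MetricReport(
        rmsd=rmsd_contours(auto_contour, manual_contour),
        ccc=ccc_masks(auto_mask, manual_mask),
        pe=percent_error(auto_mask, manual_mask),
        es=error_sum(auto_mask, manual_mask),
        n_points=n,
    )


def summarize_reports(reports: Sequence[MetricReport]) -> dict[str, tuple[float, float]]:
    """Mean ± (population) standard deviation per metric over an image set."""
    if not reports:
        raise ValidationError("cannot summarize an empty report list")
    out = {}
    for name in ("rmsd", "ccc", "pe", "es"):
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        out[name] = (float(vals.mean()), float(vals.std()))
    return out
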