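"""Five-stage preprocessing chain turning raw echo frames into watershed input.

The chain is: ECG-synchronized time averaging over two cardiac cycles →
shift-invariant wavelet denoising (optional for high-quality images) →
self-reinforcing Laplacian-of-Gaussian edge enhancement → grayscale
morphological smoothing → homotopy modification (minima imposition at
below-median regional minima).  Every stage maps [0, 1] images to [0, 1]
images of the same shape and is the identity on constant images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage as ndi
from skimage.morphology import local_minima, reconstruction

from .errors import ValidationError
from .io_sequences import EchoSequence, as_image

__all__ = [
    "PreprocessConfig",
    "PreprocessedFrame",
    "disk",
    "time_average",
    "wavelet_denoise",
    "edge_enhance_log",
    "morph_smooth",
    "homotopy_modify",
    "preprocess_frame",
    "preprocess_cycle",
]

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    Defaults follow the reference pipeline: 12th-order Daubechies wavelet
    with 4 stationary decomposition levels and soft universal thresholding,
    LoG sharpening at scale ``log_sigma`` pixels with unit gain, and a
    close(1) → open(1) → close(3) grayscale morphology schedule with
    Euclidean-disk structuring elements.
    """

    wavelet_name: str = "db12"
    wavelet_levels: int = 4
    log_sigma: float = 2.0
    log_gain: float = 1.0
    r_open_close: int = 1
    r_final_close: int = 3
    enable_wavelet: bool = True

    def __post_init__(self) -> None:
        if self.wavelet_levels < 1:
            raise ValidationError("wavelet_levels must be >= 1")
        if not self.log_sigma > 0:
            raise ValidationError("log_sigma must be positive")
        if self.log_gain < 0:
            raise ValidationError("log_gain must be nonnegative")
        if self.r_open_close < 1 or self.r_final_close < 1:
            raise ValidationError("structuring-element radii must be >= 1")


def disk(radius: int) -> np.ndarray:
    """Euclidean disk structuring element: offsets (i, j) with i²+j² <= r²."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx <= r * r).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stage 1: ECG-synchronized time averaging
# ---------------------------------------------------------------------------

def _cycle_frame_pairs(seq: EchoSequence, k: int) -> list[int]:
    """Absolute frame indices entering the four-frame average for index ``k``.

    Frames ``k`` and ``k+1`` of each of the two R-wave-aligned cycles are
    averaged; at a cycle's last frame, ``k+1`` wraps to the cycle's first
    frame (cardiac periodicity).  If the second cycle is shorter than the
    first, indices beyond its end fall back to two-frame averaging within
    cycle 1.
    """
    (c1s, c1e), (c2s, c2e) = seq.cycle_bounds()
    len1, len2 = c1e - c1s, c2e - c2s
    if len1 < 1 or len2 < 1:
        raise ValidationError("each cardiac cycle must contain at least one frame")
    if not 0 <= k < len1:
        raise ValidationError(f"frame index {k} outside cycle 1 (length {len1})")
    idx = [c1s + k, c1s + (k + 1) % len1]
    if k < len2:
        idx += [c2s + k, c2s + (k + 1) % len2]
    return idx


def time_average(seq: EchoSequence, k: int) -> np.ndarray:
    """Pixelwise mean of frames ``k``/``k+1`` from two R-wave-aligned cycles."""
    idx = _cycle_frame_pairs(seq, k)
    return seq.frames[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# Stage 2: shift-invariant wavelet denoising
# ---------------------------------------------------------------------------

def wavelet_denoise(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Denoise with the undecimated (stationary) 2-D wavelet transform.

    Detail coefficients at every level are soft-thresholded at the universal
    threshold sigma·sqrt(2·log n), with the noise scale sigma estimated from
    the median absolute deviation of the finest diagonal band.  The
    stationary transform makes the result equivariant to circular shifts
    (exactly so when no boundary padding is needed).
    """
    img = as_image(img)
    h, w = img.shape
    block = 2 ** cfg.wavelet_levels
    if min(h, w) < block:
        raise ValidationError(
            f"image {img.shape} too small for {cfg.wavelet_levels} wavelet levels"
        )
    pad_h = (-h) % block
    pad_w = (-w) % block
    padded = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect") if pad_h or pad_w else img

    coeffs = pywt.swt2(
        padded, cfg.wavelet_name, level=cfg.wavelet_levels, trim_approx=True, norm=True
    )
    # Noise scale from the finest diagonal band; with the normalized
    # transform the band noise level halves with every coarser level, so the
    # universal threshold is applied per level on that scale.
    finest_diag = coeffs[-1][2]
    sigma = np.median(np.abs(finest_diag)) / 0.6745
    if sigma < 1.0 / 65535:
        # Estimated noise below the quantization step of even 16-bit input:
        # nothing to denoise, and skipping the transform round trip keeps
        # the stage an exact identity on clean images.
        return img.copy()
    if sigma > 0:
        factor = np.sqrt(2.0 * np.log(padded.size))
        n_detail = len(coeffs) - 1
        coeffs = [coeffs[0]] + [
            tuple(
                pywt.threshold(band, sigma * 2.0 ** (i - n_detail) * factor, mode="soft")
                for band in level
            )
            for i, level in enumerate(coeffs[1:], start=1)
        ]
    out = pywt.iswt2(coeffs, cfg.wavelet_name, norm=True)
    out = out[:h, :w]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Stage 3: self-reinforcing Laplacian-of-Gaussian edge enhancement
# ---------------------------------------------------------------------------

def edge_enhance_log(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Sharpen edges: ``clip(m - gain * (LoG_sigma * m), [0, 1])``.

    Subtracting the Laplacian-of-Gaussian response steepens intensity steps
    (overshoot on the bright side, undershoot on the dark side), which
    highlights the cavity/myocardium interface.  The kernel is truncated at
    4 sigma and borders are handled by reflection.  With ``log_gain = 0``
    this is the identity.
    """
    img = as_image(img)
    if cfg.log_gain == 0:
        return img.copy()
    kernel = _log_kernel(cfg.log_sigma)
    response = ndi.convolve(img, kernel, mode="reflect")
    return np.clip(img - cfg.log_gain * response, 0.0, 1.0)


def _log_kernel(sigma: float) -> np.ndarray:
    """Discrete LoG kernel truncated at 4 sigma, corrected to sum to zero
    (so the filter responds only to structure, never to the mean level)."""
    r = int(np.ceil(4.0 * sigma))
    impulse = np.zeros((2 * r + 1, 2 * r + 1))
    impulse[r, r] = 1.0
    kernel = ndi.gaussian_laplace(impulse, sigma, mode="constant", truncate=4.0)
    return kernel - kernel.mean()


# ---------------------------------------------------------------------------
# Stage 4: grayscale morphological smoothing
# ---------------------------------------------------------------------------

def morph_smooth(img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Grayscale closing(r=1) → opening(r=1) → closing(r=3).

    Removes isolated single-pixel extrema and attenuates small local
    contrast variations that would otherwise seed spurious watershed basins.
    """
    img = as_image(img)
    se_small = disk(cfg.r_open_close)
    se_large = disk(cfg.r_final_close)
    out = ndi.grey_closing(img, footprint=se_small, mode="reflect")
    out = ndi.grey_opening(out, footprint=se_small, mode="reflect")
    out = ndi.grey_closing(out, footprint=se_large, mode="reflect")
    return out


# ---------------------------------------------------------------------------
# Stage 5: homotopy modification (minima imposition)
# ---------------------------------------------------------------------------

def homotopy_modify(
    img: np.ndarray, *, consolidate: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Suppress regional minima above the median; impose the rest as markers.

    The threshold is the lower-median pixel intensity (in a frame focused on
    the left ventricle at least half the pixels belong to dark blood pool,
    so the median separates cavity-level minima from bright-tissue noise
    minima).  Markers are seeded at the 8-connected regional-minimum
    components whose value is at or below the threshold; with
    ``consolidate=True`` (the default) each marker is grown to the full
    connected component of the sub-threshold set that contains it, with
    enclosed above-threshold islands filled.  Consolidation is what makes
    the stage an anti-supersegmentation device on real speckle: residual
    texture leaves many separate shallow minima inside one blood pool, and
    seeding each individually would dam the pool into fragments.  With
    ``consolidate=False`` the raw minimum components themselves are the
    markers.  Minima imposition via grayscale reconstruction by erosion then
    leaves the marker components as the image's only regional minima.

    Returns
    -------
    (imposed_image, marker_mask)
    """
    img = as_image(img)
    if img.max() - img.min() <= 1e-9:
        # Degenerate plateau (constant image, up to float rounding from the
        # earlier convolution stages): everything is one minimum.
        return img.copy(), np.ones_like(img, dtype=np.uint8)
    flat = np.sort(img, axis=None)
    threshold = flat[(flat.size - 1) // 2]  # lower median

    minima = local_minima(img, connectivity=2)
    markers = minima & (img <= threshold)
    if not markers.any():
        raise ValidationError("no regional minimum at or below the median intensity")
    if consolidate:
        # Every sub-threshold component contains at least one sub-threshold
        # regional minimum and vice versa, so this groups the raw markers by
        # sub-threshold connectivity; a small closing bridges the speckle
        # gaps inside one blood pool and hole filling absorbs enclosed
        # above-threshold islands.  The closing radius is kept well below
        # the myocardial wall thickness so distinct chambers stay separate.
        sub = img <= threshold
        sub = ndi.binary_closing(sub, structure=disk(3).astype(bool)) | sub
        markers = ndi.binary_fill_holes(sub, structure=_CONN8)

    # Minima imposition (Soille): reconstruct by erosion the marker function
    # (0 on markers, high elsewhere) constrained by min(img + delta, marker fn),
    # then rescale back into [0, 1].
    delta = 1.0
    fm = np.where(markers, 0.0, 1.0 + delta)
    constraint = np.minimum(img + delta, fm)
    imposed = reconstruction(fm, constraint, method="erosion", footprint=_CONN8)
    return imposed / (1.0 + delta), markers.astype(np.uint8)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedFrame:
    """Output of the preprocessing chain for one within-cycle frame index."""

    k: int
    averaged: np.ndarray  # stage-1 time-averaged frame (intensity source for contour correction)
    image: np.ndarray  # homotopy-modified image fed to the watershed
    markers: np.ndarray  # binary marker mask (uint8) seeding the flood


def preprocess_frame(
    seq: EchoSequence,
    k: int,
    cfg: PreprocessConfig = PreprocessConfig(),
    *,
    full: bool = False,
) -> np.ndarray | PreprocessedFrame:
    """Run the five preprocessing stages for within-cycle frame ``k``.

    Returns the homotopy-modified image, or the full
    :class:`PreprocessedFrame` (including the time-averaged frame and the
    marker mask) when ``full=True``.
    """
    averaged = time_average(seq, k)
    out = wavelet_denoise(averaged, cfg) if cfg.enable_wavelet else averaged
    out = edge_enhance_log(out, cfg)
    out = morph_smooth(out, cfg)
    imposed, markers = homotopy_modify(out)
    if full:
        return PreprocessedFrame(k=k, averaged=averaged, image=imposed, markers=markers)
    return imposed


def preprocess_cycle(
    seq: EchoSequence, cfg: PreprocessConfig = PreprocessConfig()
) -> list[PreprocessedFrame]:
    """Preprocess every frame of cycle 1 (reusable across segmentation runs).

    Preprocessing is independent of the atrioventricular barrier, so repeated
    segmentations of the same sequence (e.g. the operator-variability
    harness) can share this computation.
    """
    (c1s, c1e), _ = seq.cycle_bounds()
    return [preprocess_frame(seq, k, cfg, full=True) for k in range(c1e - c1s)]
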