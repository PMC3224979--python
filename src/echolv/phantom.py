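"""Synthetic beating-heart phantom with ground truth, plus the operator-variability harness.

The phantom emulates an apical 4-chamber acquisition zoomed on the left
ventricle: a dark blood pool (truncated ellipse with an apical taper) inside
bright myocardium, a dark atrium below the mitral plane, a dark scan-sector
background outside the myocardial shell, periodic area change over the
cycle driven by longitudinal (base-to-apex) shortening, a mitral gap opening
during diastole that connects ventricle and atrium, fully developed
multiplicative speckle, and two near-identical consecutive cycles with
R-wave frame markers at 44 frames/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .avc import avf_from_curve, build_avc, compute_avf
from .errors import SegmentationError, ValidationError
from .io_sequences import EchoSequence
from .preprocess import PreprocessConfig, PreprocessedFrame, preprocess_cycle
from .segment import Barrier, segment_sequence

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "generate_phantom",
    "true_initial_barrier",
    "VariabilityReport",
    "barrier_perturbation_harness",
]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic echo sequence.

    Defaults reproduce the study conditions: 256×256 frames, 37 frames per
    cycle at 44 Hz over two cycles, end-diastolic/end-systolic cavity area
    fractions 0.20/0.128 (true area variation fraction 36%), mitral gap open
    during the filling phase (cycle fraction 0.5–0.95), and multiplicative
    speckle of dispersion 0.15.
    """

    image_size: tuple[int, int] = (256, 256)
    frames_per_cycle: int = 37
    n_cycles: int = 2
    frame_rate: float = 44.0
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    ed_area_frac: float = 0.20
    es_area_frac: float = 0.128
    es_phase: float = 0.35
    valve_open_window: tuple[float, float] = (0.5, 0.95)
    valve_gap_width: int = 20
    cavity_intensity: float = 0.10
    muscle_intensity: float = 0.70
    atrium_intensity: float = 0.10
    background_intensity: float = 0.10
    endocardium_intensity: float = 1.0  # specular blood/tissue interface line
    speckle_scale: float = 0.15
    cycle_jitter: float = 0.02
    seed: int = 0
    # Geometry details (pixels unless noted).
    apex_row: int = 10
    trunc_frac: float = 0.6  # base truncation of the cavity ellipse, fraction of the semi-axis
    cavity_halfwidth: int | None = None  # default: width // 5
    wall_thickness: int = 8
    # Thick myocardial shell: bright tissue fills just under half the frame,
    # as in an acquisition zoomed on the ventricle, so the median intensity
    # sits at the top of the blood-pool mode at every cardiac phase.
    shell_thickness: int = 40
    endocardium_thickness: int = 4
    # Mitral recess: the valve segment of the basal border sits slightly
    # apical of the lateral hinge corners (annulus saddle), so the cavity's
    # lowest pixels — which drive barrier tracking — are the corners.
    recess_halfwidth: int = 24
    recess_depth: int = 5
    atrium_halfwidth: int | None = None  # default: width // 8
    atrium_bottom_margin: int = 10
    smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.es_area_frac < self.ed_area_frac < 1.0):
            raise ValidationError(
                "area fractions must satisfy 0 < es_area_frac < ed_area_frac < 1"
            )
        for name in ("cavity_intensity", "muscle_intensity", "atrium_intensity",
                     "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.frames_per_cycle < 8:
            raise ValidationError("frames_per_cycle must be >= 8")
        if not 0.0 < self.es_phase < 1.0:
            raise ValidationError("es_phase must lie in (0, 1)")
        if self.speckle_scale < 0 or self.cycle_jitter < 0:
            raise ValidationError("noise parameters must be nonnegative")

    @property
    def halfwidth(self) -> int:
        return self.cavity_halfwidth if self.cavity_halfwidth is not None else self.image_size[1] // 5

    @property
    def atrium_hw(self) -> int:
        return self.atrium_halfwidth if self.atrium_halfwidth is not None else self.image_size[1] // 8


@dataclass
class GroundTruth:
    """Per-frame truth of the phantom run."""

    cavity_masks: np.ndarray  # (n_frames, H, W) uint8
    areas_cm2: np.ndarray  # (n_frames,)
    valve_open: np.ndarray  # (n_frames,) bool
    valve_rows: np.ndarray  # (n_frames,) int — mitral-plane row (basal-wall midline)
    ed_index: int
    es_index: int
    true_avf: float = field(init=False)

    def __post_init__(self) -> None:
        self.true_avf = compute_avf(
            float(self.areas_cm2[self.ed_index]), float(self.areas_cm2[self.es_index])
        )

    # The time-averaging filter composites frames k and k+1 (cyclically), so
    # a composite frame's effective valve state spans its averaging window.
    def valve_open_any_window(self, k: int) -> bool:
        """True if any frame in composite frame ``k``'s window has an open valve."""
        n = len(self.valve_open)
        return bool(self.valve_open[k] or self.valve_open[(k + 1) % n])

    def valve_open_full_window(self, k: int) -> bool:
        """True if every frame in composite frame ``k``'s window has an open valve."""
        n = len(self.valve_open)
        return bool(self.valve_open[k] and self.valve_open[(k + 1) % n])

    def window_valve_row(self, k: int) -> int:
        """Basal (hinge) row of composite frame ``k``: the window's highest base."""
        n = len(self.valve_rows)
        return int(min(self.valve_rows[k], self.valve_rows[(k + 1) % n]))


def _area_fraction(phase: float, p: PhantomParams) -> float:
    """Smooth two-phase cavity-area profile: systolic shrink, diastolic refill."""
    ed, es, pes = p.ed_area_frac, p.es_area_frac, p.es_phase
    if phase <= pes:
        w = 0.5 * (1.0 - math.cos(math.pi * phase / pes))
        return ed + (es - ed) * w
    w = 0.5 * (1.0 - math.cos(math.pi * (phase - pes) / (1.0 - pes)))
    return es + (ed - es) * w


def _cavity_mask(a: float, p: PhantomParams) -> np.ndarray:
    """Rasterize the cavity: ellipse with vertical semi-axis ``a``, apex at
    ``apex_row``, truncated flat at ``trunc_frac`` of the semi-axis below center."""
    h, w = p.image_size
    b = p.halfwidth
    cx = w / 2.0
    yc = p.apex_row + a
    yy, xx = np.mgrid[0:h, 0:w]
    ell = ((xx - cx) / b) ** 2 + ((yy - yc) / a) ** 2 <= 1.0
    y_base = yc + p.trunc_frac * a
    cavity = ell & (yy <= y_base)
    # Valve recess: raise the basal border by recess_depth over the central
    # valve segment, leaving the lateral hinge corners as the lowest points.
    central = np.abs(xx - cx) <= p.recess_halfwidth
    cavity &= ~(central & (yy > y_base - p.recess_depth))
    return cavity


def _solve_semi_axis(target_px: int, p: PhantomParams) -> float:
    """Find the vertical semi-axis whose rasterized cavity has ~target_px pixels."""
    h, _ = p.image_size
    lo, hi = 4.0, (h - p.apex_row - p.wall_thickness - 2) / (1.0 + p.trunc_frac)
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        if int(_cavity_mask(mid, p).sum()) < target_px:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_phantom(params: PhantomParams = PhantomParams()) -> tuple[EchoSequence, GroundTruth]:
    """Generate the phantom sequence and its ground truth.

    Deterministic given ``params.seed``: every frame's speckle draws from its
    own substream (one ``SeedSequence`` child per frame), so per-frame noise
    does not depend on evaluation order.  Cycle 2 repeats cycle 1's geometry
    with independent speckle and a small cycle-wide intensity offset.
    """
    p = params
    h, w = p.image_size
    fpc = p.frames_per_cycle
    n_frames = fpc * p.n_cycles
    dy, dx = p.pixel_spacing
    px_area_cm2 = dy * dx / 100.0
    cx = w // 2

    children = np.random.SeedSequence(p.seed).spawn(n_frames + 1)
    jitter_rng = np.random.default_rng(children[-1])
    cycle_offsets = [0.0] + [
        float(jitter_rng.uniform(-p.cycle_jitter, p.cycle_jitter))
        for _ in range(p.n_cycles - 1)
    ]

    clean_frames: list[np.ndarray] = []
    masks = np.zeros((fpc, h, w), dtype=np.uint8)
    valve_open = np.zeros(fpc, dtype=bool)
    valve_rows = np.zeros(fpc, dtype=np.int64)
    atrium_bottom = h - p.atrium_bottom_margin

    for k in range(fpc):
        phase = k / fpc
        target = int(round(_area_fraction(phase, p) * h * w))
        a = _solve_semi_axis(target, p)
        cavity = _cavity_mask(a, p)
        y_base = int(math.floor(p.apex_row + (1.0 + p.trunc_frac) * a))
        valve_rows[k] = y_base  # hinge-corner row: the cavity's lowest pixels

        atrium_top = y_base + p.wall_thickness
        yy, xx = np.mgrid[0:h, 0:w]
        yca = 0.5 * (atrium_top + atrium_bottom)
        sa = max(0.5 * (atrium_bottom - atrium_top), 1.0)
        atrium = ((xx - cx) / p.atrium_hw) ** 2 + ((yy - yca) / sa) ** 2 <= 1.0

        open_now = p.valve_open_window[0] <= phase < p.valve_open_window[1]
        valve_open[k] = open_now

        interior = cavity | atrium
        if open_now:
            g = p.valve_gap_width // 2
            channel = np.zeros_like(interior)
            channel[
                y_base - p.recess_depth : atrium_top + 3,
                cx - g : cx - g + p.valve_gap_width,
            ] = True
            interior |= channel

        # Tissue layering outward from the blood pools: a thin bright
        # specular endocardial line at the blood/tissue interface, mid-gray
        # myocardium behind it, dark scan sector beyond the shell.
        dist = ndi.distance_transform_edt(~interior)
        clean = np.full((h, w), p.background_intensity)
        clean[dist <= p.shell_thickness] = p.muscle_intensity
        clean[dist <= p.endocardium_thickness] = p.endocardium_intensity
        clean[interior] = p.cavity_intensity
        clean[atrium] = p.atrium_intensity
        clean = np.clip(ndi.gaussian_filter(clean, p.smooth_sigma), 0.0, 1.0)
        clean_frames.append(clean)
        masks[k] = cavity.astype(np.uint8)

    frames = np.empty((n_frames, h, w))
    for i in range(n_frames):
        k, cyc = i % fpc, i // fpc
        clean = np.clip(clean_frames[k] + cycle_offsets[cyc], 0.0, 1.0)
        if p.speckle_scale > 0:
            rng = np.random.default_rng(children[i])
            shape = 1.0 / (p.speckle_scale**2)
            speckle = rng.gamma(shape, 1.0 / shape, size=(h, w))
            frames[i] = np.clip(clean * speckle, 0.0, 1.0)
        else:
            frames[i] = clean

    seq = EchoSequence(
        frames=frames,
        frame_rate=p.frame_rate,
        pixel_spacing=p.pixel_spacing,
        r_wave_indices=[m * fpc for m in range(p.n_cycles)],
    )
    areas = masks.reshape(fpc, -1).sum(axis=1) * px_area_cm2
    gt = GroundTruth(
        cavity_masks=masks,
        areas_cm2=areas,
        valve_open=valve_open,
        valve_rows=valve_rows,
        ed_index=int(np.argmax(areas)),
        es_index=int(np.argmin(areas)),
    )
    return seq, gt


def true_initial_barrier(
    gt: GroundTruth, params: PhantomParams = PhantomParams(), margin: int = 3
) -> Barrier:
    """Barrier spanning the mitral valve (the basal recess, plus a small
    margin) at the true hinge-plane row of frame 0.

    The barrier covers the valve's extension only — not the full basal
    width — so the lateral hinge corners stay outside it and keep driving
    the automatic vertical tracking.
    """
    mask0 = gt.cavity_masks[0]
    if not mask0.any():
        raise ValidationError("ground-truth cavity of frame 0 is empty")
    w = mask0.shape[1]
    cx = w // 2
    half = params.recess_halfwidth + margin
    return Barrier(
        x_start=max(0, cx - half),
        x_end=min(w - 1, cx + half),
        y=int(gt.valve_rows[0]),
        kind="primary",
    )


@dataclass
class VariabilityReport:
    """Summary of repeated runs with perturbed initial barriers (one row per frame)."""

    frame_indices: np.ndarray
    mean_area_cm2: np.ndarray
    std_area_percent: np.ndarray  # per-frame std across runs, percent of the mean
    avf_values: np.ndarray  # one AVF per successful run
    avf_mean: float
    avf_std: float
    n_runs: int
    n_failed: int
    barriers: list[Barrier]


def barrier_perturbation_harness(
    seq: EchoSequence,
    gt: GroundTruth,
    n_operators: int = 4,
    n_reps: int = 10,
    jitter: tuple[int, int] = (3, 2),
    seed: int = 0,
    cfg: PreprocessConfig = PreprocessConfig(),
    *,
    preprocessed: Sequence[PreprocessedFrame] | None = None,
) -> VariabilityReport:
    """Automated analogue of the intra/inter-operator barrier-placement study.

    Draws ``n_operators × n_reps`` initial barriers whose endpoints are
    jittered uniformly within ``±jitter`` pixels of the true barrier, runs
    the full pipeline for each, and summarizes per-frame mean area, per-frame
    area standard deviation (percent of the mean), and the AVF spread across
    runs.  Runs that fail outright are excluded from the statistics and
    counted in ``n_failed``.
    """
    h, w = seq.shape
    base = true_initial_barrier(gt)
    jx, jy = jitter
    rng = np.random.default_rng(seed)
    if preprocessed is None:
        preprocessed = preprocess_cycle(seq, cfg)

    barriers: list[Barrier] = []
    for _ in range(n_operators * n_reps):
        x0 = base.x_start + int(rng.integers(-jx, jx + 1)) if jx else base.x_start
        x1 = base.x_end + int(rng.integers(-jx, jx + 1)) if jx else base.x_end
        y = base.y + int(rng.integers(-jy, jy + 1)) if jy else base.y
        x0, x1 = sorted((max(0, x0), min(w - 1, x1)))
        barriers.append(Barrier(x0, x1, min(h - 1, max(0, y)), kind="primary"))

    n_frames = len(preprocessed)
    all_areas: list[np.ndarray] = []
    avfs: list[float] = []
    n_failed = 0
    for barrier in barriers:
        try:
            results = segment_sequence(seq, barrier, cfg=cfg, preprocessed=preprocessed)
            curve = build_avc(results, seq)
            avfs.append(avf_from_curve(curve, r_wave_frame=0).avf)
            all_areas.append(curve.areas)
        except (SegmentationError, ValidationError):
            n_failed += 1
    if not all_areas:
        raise SegmentationError("every perturbed-barrier run failed")

    stack = np.vstack(all_areas)
    mean_area = np.nanmean(stack, axis=0)
    std_area = np.nanstd(stack, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        std_pct = np.where(mean_area > 0, 100.0 * std_area / mean_area, 0.0)
    avf_arr = np.array(avfs)
    return VariabilityReport(
        frame_indices=np.arange(n_frames),
        mean_area_cm2=mean_area,
        std_area_percent=std_pct,
        avf_values=avf_arr,
        avf_mean=float(avf_arr.mean()),
        avf_std=float(avf_arr.std()),
        n_runs=len(avfs),
        n_failed=n_failed,
        barriers=barriers,
    )
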