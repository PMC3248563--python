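"""Seeded generators for every input the pipeline consumes, with ground truth.

The original screen's videos and images are not deposited anywhere, so every
stage of the pipeline is exercised on synthetic data that emulates the assay:

* :func:`simulate_worm_video` — dark undulating worms crawling on a bright,
  flickering plate background at known body-lengths-per-second speeds;
* :func:`simulate_foci_image` — diffuse muscle fluorescence with planted
  bright foci of known physical size;
* :func:`simulate_frap_trace` — photobleach recovery traces with a known
  mobile fraction and mild acquisition bleaching;
* :func:`simulate_screen_tables` — per-gene outcome tables with a planted
  triage structure (suppression calls, motility shifts, TS rescues).

Every generator derives one pseudo-random stream per call from
``(seed, purpose-tag)`` so that adding a generator never perturbs existing
fixtures, and identical seeds give bit-identical outputs.

The packaged reference screen scenario (:func:`default_screen_fixture`, seed
1002438) is built so that the planted genes — and only they — satisfy the
configured rules and tests; a bounded, seeded redraw guards each gene against
finite-sample flips, which makes the triage cascade recover the planted stage
memberships exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .foci import FociDetectParams, Q35_RULE, Q37_RULE, SOD1_RULE, suppression_call
from .frap import FrapTrace
from .imaging import FrameStack
from .stats import student_t_test, two_proportion_z_test
from .tables import load_table1_fixture, load_table2_fixture
from .triage import (
    FUNCTIONAL_CLASSES,
    GeneRecord,
    ScreenDataset,
    TS_STRAINS,
    TsOutcome,
)

__all__ = [
    "WormSimParams",
    "FociSimParams",
    "ScreenSimParams",
    "simulate_worm_video",
    "simulate_foci_image",
    "simulate_frap_trace",
    "simulate_screen_tables",
    "default_screen_fixture",
    "DEFAULT_SCREEN_SEED",
]

# Purpose tags for independent RNG streams per generator.
_TAG_VIDEO, _TAG_FOCI, _TAG_FRAP, _TAG_SCREEN = 11, 12, 13, 14

#: Seed of the packaged reference screen fixture.
DEFAULT_SCREEN_SEED = 1002438


def _rng(seed: int, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag), *map(int, extra)])


# ---------------------------------------------------------------------------
# Worm motility videos
# ---------------------------------------------------------------------------


@dataclass
class WormSimParams:
    """Acquisition and worm-shape parameters of a synthetic motility video.

    Defaults emulate the tracking assay: 45 s at 5 frames/s, adult worms of
    ~1 mm body length crawling with a sinusoidal posture, dark on a bright
    background with illumination flicker and Gaussian sensor noise.
    ``speed_blps`` may be a scalar (all worms) or one value per worm.
    """

    n_worms: int = 1
    body_length_um: float = 1000.0
    body_width_um: float = 70.0
    speed_blps: float | Sequence[float] = 0.15
    undulation_amplitude_um: float = 60.0
    undulation_freq_hz: float = 0.4
    undulation_periods: int = 2
    pixel_size_um: float = 12.0
    fps: float = 5.0
    duration_s: float = 45.0
    arena_px: tuple[int, int] | None = None
    roam_radius_px: float = 60.0
    background_level: float = 180.0
    worm_contrast: float = 90.0
    flicker_amplitude: float = 0.10
    noise_sigma: float = 4.0
    record_midlines: bool = False

    def speeds(self) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.speed_blps, dtype=float))
        if s.size == 1:
            s = np.repeat(s, self.n_worms)
        if s.size != self.n_worms:
            raise ValueError("speed_blps must be scalar or one value per worm")
        if np.any(s < 0):
            raise ValueError("speeds must be >= 0")
        return s


def _sine_chord_px(arc_len_px: float, amplitude_px: float, periods: int) -> float:
    """Chord length C such that y = A sin(2*pi*k*x/C), x in [0, C], has the
    requested arc length.  Bisection on the (monotone) arc-length integral."""

    def arclen(chord: float) -> float:
        x = np.linspace(0.0, chord, 801)
        slope = amplitude_px * (2 * np.pi * periods / chord) * np.cos(
            2 * np.pi * periods * x / chord
        )
        return float(np.trapezoid(np.sqrt(1.0 + slope**2), x))

    lo, hi = 1e-3 * arc_len_px, arc_len_px
    if arclen(hi) < arc_len_px:  # nearly straight worm: chord ~ arc length
        return arc_len_px
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if arclen(mid) < arc_len_px:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def _paint_worm(
    canvas: np.ndarray,
    midline: np.ndarray,
    half_width_px: float,
) -> None:
    """Accumulate soft (1-px anti-aliased edge) coverage of a thick midline.

    The body tapers to a point over roughly the last tenth of each end, as a
    real animal does, so the rendered tip-to-tip extent matches the midline
    arc length instead of overhanging it by a half-width per end.
    """
    n = len(midline)
    u = np.abs(np.linspace(-1.0, 1.0, n))
    half_widths = half_width_px * np.sqrt(np.clip(1.0 - u**10, 0.0, None))
    r0 = max(0, int(np.floor(midline[:, 0].min() - half_width_px - 2)))
    r1 = min(canvas.shape[0], int(np.ceil(midline[:, 0].max() + half_width_px + 3)))
    c0 = max(0, int(np.floor(midline[:, 1].min() - half_width_px - 2)))
    c1 = min(canvas.shape[1], int(np.ceil(midline[:, 1].max() + half_width_px + 3)))
    if r1 <= r0 or c1 <= c0:
        return
    rows = np.arange(r0, r1, dtype=np.float32)
    cols = np.arange(c0, c1, dtype=np.float32)
    mid = midline.astype(np.float32)
    d2 = (
        (rows[:, None, None] - mid[None, None, :, 0]) ** 2
        + (cols[None, :, None] - mid[None, None, :, 1]) ** 2
    )
    cov = np.clip(
        half_widths.astype(np.float32)[None, None, :] + 0.5 - np.sqrt(d2), 0.0, 1.0
    ).max(axis=2)
    np.maximum(canvas[r0:r1, c0:c1], cov, out=canvas[r0:r1, c0:c1])


def simulate_worm_video(
    params: WormSimParams, seed: int = 0
) -> tuple[FrameStack, dict]:
    """Render a crawling-worm video and return it with its ground truth.

    Worms are thick sinusoidal midlines of fixed arc length advancing at
    ``speed * body_length`` per second along smoothly turning headings.  Each
    worm is confined to its own arena cell by steering back toward the cell
    centre, so worms never touch (multi-worm contact handling is out of the
    tracker's scope).  Per-frame multiplicative flicker and additive Gaussian
    noise are applied on top of the clean render.

    Returns ``(stack, truth)`` where ``truth`` carries per-worm centroid
    trajectories in pixels, the midline arc length (the ground-truth body
    length) and the driving speeds.
    """
    p = params
    n_frames = int(round(p.fps * p.duration_s))
    if n_frames < 2:
        raise ValueError("need fps * duration_s >= 2 frames")
    if not 0 <= p.flicker_amplitude < 0.5:
        raise ValueError("flicker_amplitude must be in [0, 0.5)")
    rng = _rng(seed, _TAG_VIDEO)
    px = p.pixel_size_um
    body_px = p.body_length_um / px
    half_width_px = 0.5 * p.body_width_um / px
    amp_px = p.undulation_amplitude_um / px
    chord_px = _sine_chord_px(body_px, amp_px, p.undulation_periods)
    speeds = p.speeds()

    margin = chord_px / 2 + amp_px + half_width_px + 4
    n_cols = int(math.ceil(math.sqrt(p.n_worms)))
    n_rows = int(math.ceil(p.n_worms / n_cols))
    if p.arena_px is not None:
        height, width = p.arena_px
        cell_h, cell_w = height / n_rows, width / n_cols
        if min(cell_h, cell_w) < 2 * (margin + 5):
            raise GeometryError(
                f"arena {p.arena_px} too small for {p.n_worms} worms of "
                f"body length {p.body_length_um} um"
            )
        roam = min(p.roam_radius_px, min(cell_h, cell_w) / 2 - margin)
    else:
        roam = p.roam_radius_px
        cell_h = cell_w = 2 * (margin + roam)
        height = int(math.ceil(n_rows * cell_h))
        width = int(math.ceil(n_cols * cell_w))

    centers = np.array(
        [
            ((i // n_cols + 0.5) * cell_h, (i % n_cols + 0.5) * cell_w)
            for i in range(p.n_worms)
        ]
    )
    pos = centers + rng.uniform(-0.25, 0.25, size=centers.shape) * roam
    theta = rng.uniform(-math.pi, math.pi, size=p.n_worms)
    phase = rng.uniform(0, 2 * math.pi, size=p.n_worms)
    flicker_phase = rng.uniform(0, 2 * math.pi)

    dt = 1.0 / p.fps
    turn_sigma = 0.6  # rad / sqrt(s): smooth random heading drift
    max_turn = 1.5 * dt  # rad per frame when steering back to the cell centre
    n_samples = max(40, int(chord_px) + 1)
    xs = np.linspace(0.0, chord_px, n_samples)

    frames = np.empty((n_frames, height, width), dtype=np.float32)
    centroids = np.empty((p.n_worms, n_frames, 2))
    midlines: list[list[np.ndarray]] = [[] for _ in range(p.n_worms)]
    flicker_t = 1.0 + p.flicker_amplitude * np.sin(
        2 * np.pi * 0.8 * np.arange(n_frames) * dt + flicker_phase
    )
    for t in range(n_frames):
        canvas = np.zeros((height, width), dtype=np.float32)
        for w in range(p.n_worms):
            ys = amp_px * np.sin(
                2 * np.pi * p.undulation_periods * xs / chord_px + phase[w]
            )
            local = np.stack([ys, xs - chord_px / 2], axis=1)  # (row, col)
            cos_t, sin_t = math.cos(theta[w]), math.sin(theta[w])
            rot = np.stack(
                [
                    local[:, 0] * cos_t + local[:, 1] * sin_t,
                    -local[:, 0] * sin_t + local[:, 1] * cos_t,
                ],
                axis=1,
            )
            midline = rot + pos[w]
            _paint_worm(canvas, midline, half_width_px)
            centroids[w, t] = pos[w]
            if p.record_midlines:
                midlines[w].append(midline.copy())
            # advance state for the next frame
            theta[w] += turn_sigma * math.sqrt(dt) * rng.standard_normal()
            off = pos[w] - centers[w]
            if np.hypot(*off) > roam:
                desired = math.atan2(-off[0], -off[1])
                delta = _wrap_angle(desired - math.atan2(math.sin(theta[w]), math.cos(theta[w])))
                theta[w] += float(np.clip(delta, -max_turn, max_turn))
            step = speeds[w] * body_px * dt
            theta_w = theta[w]
            pos[w] += step * np.array([math.sin(theta_w), math.cos(theta_w)])
            phase[w] += 2 * math.pi * p.undulation_freq_hz * dt
        clean = float(flicker_t[t]) * (p.background_level - p.worm_contrast * canvas)
        noise = p.noise_sigma * rng.standard_normal(clean.shape, dtype=np.float32)
        frames[t] = np.clip(clean + noise, 0.0, None)

    stack = FrameStack(
        frames=frames,
        frame_interval_s=dt,
        pixel_size_um=px,
        meta={"generator": "simulate_worm_video", "seed": int(seed)},
    )
    truth = {
        "centroids_px": centroids,
        "body_length_um": float(p.body_length_um),
        "speeds_blps": speeds,
        "chord_px": float(chord_px),
        "half_width_px": float(half_width_px),
    }
    if p.record_midlines:
        truth["midlines_px"] = midlines
    return stack, truth


# ---------------------------------------------------------------------------
# Foci images
# ---------------------------------------------------------------------------


@dataclass
class FociSimParams:
    """Parameters of a synthetic single-animal fluorescence image.

    Planted foci are bright discs (round aggregates) or capsules (elongated
    aggregates) on diffuse muscle fluorescence with smooth texture and sensor
    noise.  ``round_area_um2`` and ``elongated_length_um`` give sampling
    ranges; explicit plant geometries can be passed to the generator instead.
    """

    image_shape: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.5
    n_foci: int = 12
    elongated_fraction: float = 0.25
    round_area_um2: tuple[float, float] = (8.0, 16.0)
    elongated_length_um: tuple[float, float] = (3.5, 6.0)
    elongated_width_um: float = 0.9
    n_sub_threshold: int = 0
    sub_threshold_area_um2: float = 3.5
    base_level: float = 100.0
    texture_sigma_um: float = 6.0
    texture_amplitude: float = 6.0
    focus_amplitude: float = 60.0
    noise_sigma: float = 3.0


@dataclass(frozen=True)
class PlantedFocus:
    """Ground truth of one planted focus."""

    centroid: tuple[float, float]  # (row, col) px
    area_um2: float
    length_um: float
    elongated: bool
    above_detection_limit: bool


def _paint_capsule(
    img: np.ndarray,
    center: tuple[float, float],
    angle: float,
    seg_half_px: float,
    half_width_px: float,
    amplitude: float,
) -> None:
    r0 = max(0, int(center[0] - seg_half_px - half_width_px - 2))
    r1 = min(img.shape[0], int(center[0] + seg_half_px + half_width_px + 3))
    c0 = max(0, int(center[1] - seg_half_px - half_width_px - 2))
    c1 = min(img.shape[1], int(center[1] + seg_half_px + half_width_px + 3))
    rr, cc = np.meshgrid(
        np.arange(r0, r1, dtype=float), np.arange(c0, c1, dtype=float), indexing="ij"
    )
    dr, dc = rr - center[0], cc - center[1]
    along = dr * math.sin(angle) + dc * math.cos(angle)
    across = dr * math.cos(angle) - dc * math.sin(angle)
    along_clamped = np.clip(along, -seg_half_px, seg_half_px)
    d = np.sqrt((along - along_clamped) ** 2 + across**2)
    cov = np.clip(half_width_px + 0.5 - d, 0.0, 1.0)
    img[r0:r1, c0:c1] += amplitude * cov


def simulate_foci_image(
    params: FociSimParams, seed: int = 0
) -> tuple[np.ndarray, list[PlantedFocus]]:
    """Render diffuse body fluorescence with planted bright foci.

    Returns ``(image, plants)``; each plant records its true centroid,
    physical size, and whether it lies above the detection-limit rule
    (area >= 7 µm² or length >= 3 µm) used by the detector defaults.
    """
    from scipy.ndimage import gaussian_filter

    p = params
    rng = _rng(seed, _TAG_FOCI)
    px = p.pixel_size_um
    h, w = p.image_shape
    img = np.full((h, w), p.base_level, dtype=np.float64)
    img += p.texture_amplitude * gaussian_filter(
        rng.standard_normal((h, w)), p.texture_sigma_um / px
    )

    limits = FociDetectParams()
    plants: list[PlantedFocus] = []
    taken: list[tuple[float, float, float]] = []  # (row, col, clearance_px)

    def place(extent_px: float) -> tuple[float, float]:
        margin = extent_px / 2 + 3.0 / px
        for _ in range(500):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all(
                math.hypot(r - tr, c - tc) > extent_px / 2 + tcl + 3.0 / px
                for tr, tc, tcl in taken
            ):
                taken.append((r, c, extent_px / 2))
                return r, c
        raise GeometryError("could not place all foci without overlap")

    def plant_round(area_um2: float) -> None:
        radius_px = math.sqrt(area_um2 / math.pi) / px
        r, c = place(2 * radius_px)
        _paint_capsule(img, (r, c), 0.0, 0.0, radius_px, p.focus_amplitude)
        length = 2 * radius_px * px
        plants.append(
            PlantedFocus(
                centroid=(r, c),
                area_um2=area_um2,
                length_um=length,
                elongated=False,
                above_detection_limit=(
                    area_um2 >= limits.min_area_um2 or length >= limits.min_length_um
                ),
            )
        )

    n_elong = int(round(p.n_foci * p.elongated_fraction))
    for _ in range(p.n_foci - n_elong):
        plant_round(rng.uniform(*p.round_area_um2))
    for _ in range(n_elong):
        length_um = rng.uniform(*p.elongated_length_um)
        width_um = p.elongated_width_um
        seg_half_px = max(0.0, (length_um - width_um) / 2) / px
        half_width_px = width_um / 2 / px
        angle = rng.uniform(0, math.pi)
        r, c = place(length_um / px)
        _paint_capsule(img, (r, c), angle, seg_half_px, half_width_px, p.focus_amplitude)
        area = (length_um - width_um) * width_um + math.pi * (width_um / 2) ** 2
        plants.append(
            PlantedFocus(
                centroid=(r, c),
                area_um2=area,
                length_um=length_um,
                elongated=True,
                above_detection_limit=(
                    area >= limits.min_area_um2 or length_um >= limits.min_length_um
                ),
            )
        )
    for _ in range(p.n_sub_threshold):
        plant_round(p.sub_threshold_area_um2)

    img += rng.normal(0.0, p.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, None), plants


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def simulate_frap_trace(
    mobile_fraction: float,
    bleach_depth: float = 0.8,
    recovery_tau_s: float = 2.0,
    noise_sigma: float = 0.02,
    seed: int = 0,
    n_prebleach: int = 10,
    n_postbleach: int = 200,
    dt_s: float = 0.12335,
    acquisition_bleach_per_frame: float = 0.0015,
    roi_baseline: float = 150.0,
    total_baseline: float = 1000.0,
) -> FrapTrace:
    """Synthesize a FRAP trace whose analytic mobile fraction is known.

    Post-bleach the true (bleaching-corrected) recovery follows

        RFI(t) = f_m * (1 - exp(-t/tau)) * (1 - RFI0) + RFI0,

    with ``RFI0 = 1 - bleach_depth``.  The whole-cell channel decays
    geometrically with frame number (mild acquisition bleaching), so the ROI
    channel is modulated accordingly and the double normalization in
    :func:`wormtriage.frap.compute_rfi` is genuinely exercised.
    Multiplicative Gaussian noise (sigma = ``noise_sigma``) is applied to the
    ROI channel and a fifth of it to the steadier whole-cell channel.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if not 0 < bleach_depth <= 1:
        raise ValueError("bleach_depth must be in (0, 1]")
    rng = _rng(seed, _TAG_FRAP)
    n = n_prebleach + n_postbleach
    frame_idx = np.arange(n)
    times = frame_idx * dt_s
    decay = (1.0 - acquisition_bleach_per_frame) ** frame_idx
    total = total_baseline * decay

    rfi0 = 1.0 - bleach_depth
    t_post = (frame_idx[n_prebleach:] - n_prebleach) * dt_s
    rfi_true = np.empty(n)
    rfi_true[:n_prebleach] = 1.0
    tau = max(recovery_tau_s, 1e-9)
    rfi_true[n_prebleach:] = (
        mobile_fraction * (1.0 - np.exp(-t_post / tau)) * (1.0 - rfi0) + rfi0
    )
    roi = roi_baseline * rfi_true * decay
    roi = roi * (1.0 + rng.normal(0.0, noise_sigma, size=n))
    total = total * (1.0 + rng.normal(0.0, noise_sigma / 5, size=n))
    return FrapTrace(
        times_s=times,
        roi_intensity=np.clip(roi, 1e-9, None),
        total_intensity=np.clip(total, 1e-9, None),
        bleach_index=n_prebleach,
    )


# ---------------------------------------------------------------------------
# Screen outcome tables
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimParams:
    """Planted structure and noise levels of the reference screen scenario.

    The default stage sizes reproduce the screen cascade: 151 genome-screen
    positives (91 strong), no soluble-reporter artifacts, 88 Class A genes
    (the bundled modifier table, 81 of them strong), 63 SOD1-common genes,
    33 wild-type-motility exclusions, a 23/20/12 suppress/no-change/enhance
    split of the 55 remaining genes, and 9 core modifiers with the bundled
    TS rescue tallies.
    """

    n_genes: int = 300
    n_animals: int = 50
    control_foci_mean: float = 35.0
    control_foci_sd: float = 4.0
    q37_control_mean: float = 45.0
    sod1_control_mean: float = 55.0
    n_q35_positive: int = 151
    n_q35_strong: int = 91
    n_strong_in_class_a: int = 81
    n_sod1: int = 63
    n_wt_excluded: int = 33
    n_toxicity: int = 23
    n_no_change: int = 20
    artifact_genes: tuple[str, ...] = ()
    n_tracks: int = 75
    wt_blps_mean: float = 0.20
    wt_blps_sd: float = 0.05
    wt_excluded_mean: float = 0.14
    q35_blps_mean: float = 0.12
    q35_blps_sd: float = 0.04
    suppress_blps_mean: float = 0.19
    enhance_blps_mean: float = 0.08
    ts_n_animals: int = 60
    ts_control_pct: float = 80.0
    ts_rescue_reduction: tuple[float, float] = (0.50, 0.70)
    ts_null_reduction: tuple[float, float] = (0.05, 0.25)
    wt_alpha: float = 0.001
    motility_alpha: float = 0.05
    ts_alpha: float = 0.01
    ts_min_reduction: float = 0.40
    max_redraws: int = 200


def _redraw(draw, check, max_tries: int, what: str):
    """Draw until ``check`` accepts; the draw closure owns its RNG stream."""
    for _ in range(max_tries):
        value = draw()
        if check(value):
            return value
    raise RuntimeError(f"could not realize planted outcome for {what}")


def _foci_counts_for_plant(
    rng: np.random.Generator,
    plant: str,
    control_mean: float,
    n_animals: int,
) -> np.ndarray:
    """Per-animal foci counts for a planted genome-screen outcome class."""
    if plant == "strong":
        red = rng.normal(0.70, 0.06, n_animals)
    elif plant == "weak":
        hit = rng.random(n_animals) < 0.62
        red = np.where(
            hit, rng.normal(0.55, 0.03, n_animals), rng.normal(0.20, 0.10, n_animals)
        )
    elif plant == "none":
        red = rng.normal(0.0, 0.12, n_animals)
    else:
        raise ValueError(plant)
    counts = np.clip(np.rint(control_mean * (1.0 - red)), 0, None)
    return counts.astype(int)


def _counter_counts_for_plant(
    rng: np.random.Generator,
    positive: bool,
    control_mean: float,
    n_animals: int,
) -> np.ndarray:
    red = (
        rng.normal(0.50, 0.08, n_animals)
        if positive
        else rng.normal(0.08, 0.08, n_animals)
    )
    return np.clip(np.rint(control_mean * (1.0 - red)), 0, None).astype(int)


def simulate_screen_tables(
    params: ScreenSimParams | None = None, seed: int = DEFAULT_SCREEN_SEED
) -> tuple[ScreenDataset, dict]:
    """Generate the per-gene outcome tables of a planted screen.

    Gene identities come from the bundled modifier tables: the 88 Class A
    genes (with their functional classes) and the 9 core modifiers with their
    TS tallies; Class B and non-hit genes carry synthetic names.  Per-animal
    foci counts, per-track BLPS samples and TS phenotype percentages are drawn
    so the planted genes — and only they — pass each stage's rule at the
    stage's default test and threshold (guarded by a bounded seeded redraw).

    Returns ``(dataset, truth)`` where ``truth`` holds the planted stage
    memberships and the expected ``stage_counts``.
    """
    p = params or ScreenSimParams()
    t1 = load_table1_fixture()
    t2 = load_table2_fixture()
    class_a = list(t1["gene"])
    class_by_gene = dict(zip(t1["gene"], t1["functional_class"]))
    core_genes = list(t2["gene"])
    core_tallies = dict(zip(t2["gene"], zip(t2["ts_rescued"], t2["ts_tested"])))
    if p.n_genes < p.n_q35_positive:
        raise ValueError("n_genes must cover all planted positives")

    non_core = [g for g in class_a if g not in core_genes]
    tox = core_genes + non_core[: p.n_toxicity - len(core_genes)]
    rest = non_core[p.n_toxicity - len(core_genes):]
    wt_excluded = rest[: p.n_wt_excluded]
    survivors_not_tox = rest[p.n_wt_excluded:]
    null_genes = survivors_not_tox[: p.n_no_change]
    enhance_genes = survivors_not_tox[p.n_no_change:]
    sod1_common = tox + rest[: p.n_sod1 - len(tox)]

    n_class_b = p.n_q35_positive - len(class_a)
    class_b = [f"wk-{i + 1:03d}" for i in range(n_class_b)]
    non_hits = [f"ns-{i + 1:03d}" for i in range(p.n_genes - p.n_q35_positive)]

    strong_a = set(core_genes)
    for g in class_a:
        if len(strong_a) >= p.n_strong_in_class_a:
            break
        strong_a.add(g)
    strong_b = set(class_b[: p.n_q35_strong - len(strong_a)])
    strong = strong_a | strong_b

    ctrl_rng = _rng(seed, _TAG_SCREEN, 0)
    q35_control = np.clip(
        np.rint(ctrl_rng.normal(p.control_foci_mean, p.control_foci_sd, p.n_animals)),
        1,
        None,
    ).astype(int)
    q37_control = np.clip(
        np.rint(ctrl_rng.normal(p.q37_control_mean, p.control_foci_sd, p.n_animals)),
        1,
        None,
    ).astype(int)
    sod1_control = np.clip(
        np.rint(ctrl_rng.normal(p.sod1_control_mean, p.control_foci_sd, p.n_animals)),
        1,
        None,
    ).astype(int)
    wt_control = ctrl_rng.normal(p.wt_blps_mean, p.wt_blps_sd, p.n_tracks)
    q35_motility_control = ctrl_rng.normal(p.q35_blps_mean, p.q35_blps_sd, p.n_tracks)

    genes = class_a + class_b + non_hits
    records: list[GeneRecord] = []
    for i, gene in enumerate(genes):
        in_hit = gene in class_a or gene in class_b
        if gene in strong:
            plant = "strong"
        elif in_hit:
            plant = "weak"
        else:
            plant = "none"

        g_rng = _rng(seed, _TAG_SCREEN, 1, i)
        want_positive, want_strong = in_hit, gene in strong
        q35_counts = _redraw(
            lambda: _foci_counts_for_plant(
                g_rng, plant, float(q35_control.mean()), p.n_animals
            ),
            lambda c: (
                (call := suppression_call(gene, c, q35_control, Q35_RULE)).positive
                == want_positive
                and call.strong == want_strong
            ),
            p.max_redraws,
            f"{gene} q35",
        )

        q37_counts = sod1_counts = None
        wt_blps = q35_blps = None
        ts_outcomes: dict[str, TsOutcome] = {}
        if in_hit:
            want_a = gene in class_by_gene
            q37_counts = _redraw(
                lambda: _counter_counts_for_plant(
                    g_rng, want_a, float(q37_control.mean()), p.n_animals
                ),
                lambda c: suppression_call(gene, c, q37_control, Q37_RULE).positive
                == want_a,
                p.max_redraws,
                f"{gene} q37",
            )
        if gene in class_by_gene:
            want_sod1 = gene in sod1_common
            sod1_counts = _redraw(
                lambda: _counter_counts_for_plant(
                    g_rng, want_sod1, float(sod1_control.mean()), p.n_animals
                ),
                lambda c: suppression_call(gene, c, sod1_control, SOD1_RULE).positive
                == want_sod1,
                p.max_redraws,
                f"{gene} sod1",
            )
            want_excluded = gene in wt_excluded
            wt_mean = p.wt_excluded_mean if want_excluded else p.wt_blps_mean
            wt_blps = _redraw(
                lambda: g_rng.normal(wt_mean, p.wt_blps_sd, p.n_tracks),
                lambda s: (
                    student_t_test(s, wt_control).p_value < p.wt_alpha
                )
                == want_excluded,
                p.max_redraws,
                f"{gene} wt motility",
            )
            if not want_excluded:
                if gene in tox:
                    m_mean, want_class = p.suppress_blps_mean, "suppress"
                elif gene in null_genes:
                    m_mean, want_class = p.q35_blps_mean, "no_change"
                else:
                    m_mean, want_class = p.enhance_blps_mean, "enhance"

                def motility_class(sample: np.ndarray) -> str:
                    res = student_t_test(sample, q35_motility_control)
                    if res.p_value >= p.motility_alpha:
                        return "no_change"
                    higher = sample.mean() > q35_motility_control.mean()
                    return "suppress" if higher else "enhance"

                q35_blps = _redraw(
                    lambda: g_rng.normal(m_mean, p.q35_blps_sd, p.n_tracks),
                    lambda s: motility_class(s) == want_class,
                    p.max_redraws,
                    f"{gene} q35 motility",
                )
        if gene in tox:
            n_rescued = core_tallies.get(gene, (0, len(TS_STRAINS)))[0]
            for k, strain in enumerate(TS_STRAINS):
                want_rescue = k < n_rescued
                lo, hi = (
                    p.ts_rescue_reduction if want_rescue else p.ts_null_reduction
                )

                def ts_outcome() -> TsOutcome:
                    control_pct = float(
                        np.clip(g_rng.normal(p.ts_control_pct, 3.0), 60.0, 95.0)
                    )
                    reduction = g_rng.uniform(lo, hi)
                    return TsOutcome(
                        strain=strain,
                        pct_phenotype_treated=control_pct * (1.0 - reduction),
                        pct_phenotype_control=control_pct,
                        n_animals=p.ts_n_animals,
                    )

                def is_rescue(o: TsOutcome) -> bool:
                    reduction = 1.0 - o.pct_phenotype_treated / o.pct_phenotype_control
                    k_t = int(round(o.pct_phenotype_treated / 100 * o.n_animals))
                    k_c = int(round(o.pct_phenotype_control / 100 * o.n_animals))
                    res = two_proportion_z_test(k_t, o.n_animals, k_c, o.n_animals)
                    return (
                        reduction >= p.ts_min_reduction and res.p_value < p.ts_alpha
                    )

                ts_outcomes[strain] = _redraw(
                    ts_outcome,
                    lambda o: is_rescue(o) == want_rescue,
                    p.max_redraws,
                    f"{gene} ts {strain}",
                )

        records.append(
            GeneRecord(
                gene_id=gene,
                functional_class=class_by_gene.get(
                    gene, FUNCTIONAL_CLASSES[i % len(FUNCTIONAL_CLASSES)]
                ),
                q35_counts=q35_counts,
                q37_counts=q37_counts,
                sod1_counts=sod1_counts,
                q24_artifact=gene in p.artifact_genes,
                wt_blps=wt_blps,
                q35_blps=q35_blps,
                ts_outcomes=ts_outcomes,
            )
        )

    dataset = ScreenDataset(
        records=records,
        q35_control_counts=q35_control,
        q37_control_counts=q37_control,
        sod1_control_counts=sod1_control,
        wt_control_blps=wt_control,
        q35_control_blps=q35_motility_control,
    )
    truth = {
        "q35_positives": set(class_a) | set(class_b),
        "q35_strong": set(strong),
        "excluded_by_q24": set(p.artifact_genes),
        "class_a": set(class_a),
        "class_b": set(class_b),
        "sod1_common": set(sod1_common),
        "wt_motility_excluded": set(wt_excluded),
        "toxicity_suppressors": set(tox),
        "no_change": set(null_genes),
        "enhancers": set(enhance_genes),
        "core_modifiers": set(core_genes),
        "stage_counts": {
            "q35_positives": p.n_q35_positive,
            "class_a": len(class_a),
            "sod1_common": p.n_sod1,
            "wt_motility_pass": len(class_a) - p.n_wt_excluded,
            "toxicity_suppressors": p.n_toxicity,
            "core_modifiers": len(core_genes),
        },
    }
    return dataset, truth


def default_screen_fixture() -> tuple[ScreenDataset, dict]:
    """The packaged reference screen scenario (seed ``DEFAULT_SCREEN_SEED``)."""
    return simulate_screen_tables(ScreenSimParams(), seed=DEFAULT_SCREEN_SEED)
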