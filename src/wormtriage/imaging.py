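"""Calibrated image stacks and the low-level operators shared by the worm
tracker and the foci detector.

The video model follows stereomicroscope recordings of crawling nematodes:
dark animals on a bright, slightly flickering background.  The standard
pre-processing chain is

1. :func:`deflicker` — rescale every frame to the stack-wide mean intensity;
2. :func:`estimate_background` — per-pixel temporal maximum, which erases the
   transient dark animals and leaves the clean plate;
3. :func:`subtract_background` — ``clip(background - frame, 0)``, turning the
   animals into bright objects on a near-zero background;
4. :func:`otsu_threshold` + :func:`label_components` — binarize and extract
   connected blobs.

All physical measurements (:func:`blob_geometry`) are expressed in µm / µm²
via the mandatory pixel calibration; nothing is thresholded in raw pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage import measure
from skimage.morphology import skeletonize

from .errors import (
    DegenerateFrameError,
    DimensionError,
    InsufficientFramesError,
    NoContrastError,
)

__all__ = [
    "FrameStack",
    "Blob",
    "BlobGeometry",
    "deflicker",
    "estimate_background",
    "subtract_background",
    "otsu_threshold",
    "label_components",
    "blob_geometry",
    "max_feret_px",
    "skeleton_longest_path_px",
]


@dataclass
class FrameStack:
    """A calibrated time-lapse intensity volume.

    Parameters
    ----------
    frames
        3-D array indexed ``(time, row, col)``; finite, non-negative.
    frame_interval_s
        Seconds between consecutive frames (0.2 s for 5 fps video).
    pixel_size_um
        Micrometres per pixel edge.
    meta
        Free-form acquisition tags.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        # Preserve float32 input (large videos); everything else becomes float64.
        arr = np.asarray(self.frames)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.frames = arr
        if self.frames.ndim != 3:
            raise DimensionError(
                f"frames must be (time, row, col); got ndim={self.frames.ndim}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("frame intensities must be non-negative")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """Return a copy of this stack holding ``frames`` (same calibration)."""
        return replace(self, frames=np.asarray(frames))


@dataclass(frozen=True)
class Blob:
    """A connected foreground component in one frame.

    ``coords`` holds the ``(row, col)`` integer pixel coordinates, one row per
    pixel.  ``centroid`` is the (sub-pixel) pixel-mean position.
    """

    frame_index: int
    centroid: tuple[float, float]
    area_px: int
    perimeter_px: float
    coords: np.ndarray
    bbox: tuple[int, int, int, int]

    @property
    def pixels(self) -> set[tuple[int, int]]:
        """Pixel set view of ``coords`` (convenience for small blobs)."""
        return {(int(r), int(c)) for r, c in self.coords}

    def mask(self) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean crop of this blob and the (row, col) offset of its origin."""
        r0, c0, r1, c1 = self.bbox
        m = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        m[self.coords[:, 0] - r0, self.coords[:, 1] - c0] = True
        return m, (r0, c0)


@dataclass(frozen=True)
class BlobGeometry:
    """Physical-unit geometry of a blob: area, longest caliper, skeleton path."""

    area_um2: float
    max_feret_um: float
    skeleton_length_um: float


def deflicker(stack: FrameStack) -> FrameStack:
    """Normalize illumination flicker by rescaling each frame to the stack mean.

    Every frame is multiplied by ``stack_mean / frame_mean`` so that all frames
    share the global mean intensity.  The operation is idempotent and preserves
    the total stack mean.

    Raises
    ------
    DegenerateFrameError
        If any frame has zero mean (nothing to rescale).
    """
    means = stack.frames.mean(axis=(1, 2), dtype=np.float64)
    zero = np.flatnonzero(means == 0)
    if zero.size:
        raise DegenerateFrameError(int(zero[0]))
    target = float(stack.frames.mean(dtype=np.float64))
    scale = (target / means).astype(stack.frames.dtype)
    return stack.with_frames(stack.frames * scale[:, None, None])


def estimate_background(stack: FrameStack) -> np.ndarray:
    """Worm-free background: the per-pixel maximum over time.

    Animals are darker than the plate, and they move, so the temporal maximum
    at each pixel recovers the clean background wherever a worm does not sit
    for the whole recording.  Requires at least two frames.
    """
    if stack.n_frames < 2:
        raise InsufficientFramesError(
            "background estimation requires >= 2 frames (worms must move)"
        )
    return stack.frames.max(axis=0)


def subtract_background(stack: FrameStack, background: np.ndarray) -> FrameStack:
    """``clip(background - frame, 0)`` for every frame.

    Dark animals become bright objects on a near-zero background.  Pixels
    brighter than the background (noise) are clamped to zero rather than
    folded back with an absolute value.
    """
    background = np.asarray(background, dtype=stack.frames.dtype)
    if background.shape != stack.frame_shape:
        raise DimensionError(
            f"background shape {background.shape} != frame shape {stack.frame_shape}"
        )
    return stack.with_frames(np.clip(background[None] - stack.frames, 0.0, None))


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram spanning ``[min, max]``.

    The returned value is the *upper edge* of the winning bin, so that
    ``image > threshold`` selects the foreground class.  This mirrors 8-bit
    ImageJ behaviour while accepting float input.  Ties between bins are
    resolved toward the lowest threshold.

    Raises
    ------
    NoContrastError
        If the image is constant.
    """
    values = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise NoContrastError("constant image has no Otsu threshold")
    hist, edges = np.histogram(values, bins=256, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    omega = np.cumsum(p)                # weight of the background class
    mu = np.cumsum(p * centers)         # first moment of the background class
    mu_t = mu[-1]
    # Between-class variance for a split after bin k (k = 0..254).
    omega_k = omega[:-1]
    mu_k = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega_k - mu_k) ** 2 / (omega_k * (1.0 - omega_k))
    sigma_b[(omega_k <= 0) | (omega_k >= 1)] = -np.inf
    k = int(np.argmax(sigma_b))  # argmax takes the first maximum -> lowest bin
    return float(edges[k + 1])


_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_components(
    binary_frame: np.ndarray,
    connectivity: int = 8,
    min_area_px: int = 1,
    frame_index: int = 0,
) -> list[Blob]:
    """Extract connected foreground components as :class:`Blob` objects.

    Components smaller than ``min_area_px`` are discarded.  Output order is
    deterministic: ascending ``(min_row, min_col)`` of the bounding box.
    """
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    binary = np.asarray(binary_frame).astype(bool)
    labels, _ = ndimage.label(binary, structure=_STRUCTURE[connectivity])
    blobs: list[Blob] = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        crop = labels[sl] == i
        area = int(crop.sum())
        if area < min_area_px:
            continue
        r0, c0 = sl[0].start, sl[1].start
        local = np.argwhere(crop)
        coords = local + (r0, c0)
        centroid = coords.mean(axis=0)
        perimeter = float(measure.perimeter(crop, neighborhood=4))
        bbox = (r0, c0, sl[0].stop, sl[1].stop)
        blobs.append(
            Blob(
                frame_index=frame_index,
                centroid=(float(centroid[0]), float(centroid[1])),
                area_px=area,
                perimeter_px=perimeter,
                coords=coords,
                bbox=bbox,
            )
        )
    blobs.sort(key=lambda b: (b.bbox[0], b.bbox[1]))
    return blobs


def max_feret_px(coords: np.ndarray) -> float:
    """Longest distance between two pixel centres of a blob, in pixels."""
    pts = np.asarray(coords, dtype=np.float64)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 400:
        # Only boundary extremes can realize the maximum; the convex hull of
        # the pixel centres is a cheap exact reduction.
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear blob: brute force below is still fine
    return float(cdist(pts, pts).max())


def skeleton_longest_path_px(mask: np.ndarray) -> float:
    """Length of the longest geodesic path of the morphological skeleton.

    The skeleton is an 8-connected pixel graph with orthogonal steps of length
    1 and diagonal steps of length sqrt(2).  The longest path is found with the
    standard double-sweep (tree-diameter) heuristic, exact on acyclic
    skeletons.  A single-pixel skeleton has length 0.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    skel = skeletonize(np.asarray(mask).astype(bool))
    pts = np.argwhere(skel)
    n = len(pts)
    if n <= 1:
        return 0.0
    index = -np.ones(skel.shape, dtype=np.int64)
    index[pts[:, 0], pts[:, 1]] = np.arange(n)
    rows, cols, data = [], [], []
    h, w = skel.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r2 = pts[:, 0] + dr
        c2 = pts[:, 1] + dc
        ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
        src = np.flatnonzero(ok)
        dst = index[r2[ok], c2[ok]]
        hit = dst >= 0
        if not hit.any():
            continue
        weight = np.sqrt(2.0) if dr and dc else 1.0
        rows.extend(src[hit].tolist())
        cols.extend(dst[hit].tolist())
        data.extend([weight] * int(hit.sum()))
    if not rows:
        return 0.0
    graph = coo_matrix((data + data, (rows + cols, cols + rows)), shape=(n, n))
    d0 = dijkstra(graph, indices=0, directed=False)
    d0[~np.isfinite(d0)] = -1
    u = int(np.argmax(d0))
    du = dijkstra(graph, indices=u, directed=False)
    du[~np.isfinite(du)] = -1
    return float(du.max())


def blob_geometry(blob: Blob, pixel_size_um: float) -> BlobGeometry:
    """Physical geometry of a blob under the given pixel calibration."""
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    mask, _ = blob.mask()
    return BlobGeometry(
        area_um2=blob.area_px * pixel_size_um**2,
        max_feret_um=max_feret_px(blob.coords) * pixel_size_um,
        skeleton_length_um=skeleton_longest_path_px(mask) * pixel_size_um,
    )


def binarize_stack(
    stack: FrameStack,
    per_frame: bool = False,
) -> np.ndarray:
    """Otsu-binarize a (background-subtracted) stack.

    By default one global threshold is computed from the pooled histogram of
    all frames, which is stable when the objects occupy a small, varying area
    per frame; ``per_frame=True`` thresholds each frame independently.
    """
    if per_frame:
        out = np.empty(stack.frames.shape, dtype=bool)
        for t in range(stack.n_frames):
            out[t] = stack.frames[t] > otsu_threshold(stack.frames[t])
        return out
    thr = otsu_threshold(stack.frames)
    return stack.frames > thr


def blobs_by_frame(
    binary: np.ndarray,
    connectivity: int = 8,
    min_area_px: int = 1,
) -> list[list[Blob]]:
    """Label every frame of a binary stack; one blob list per frame."""
    return [
        label_components(binary[t], connectivity, min_area_px, frame_index=t)
        for t in range(binary.shape[0])
    ]


def iter_frames(stack: FrameStack) -> Iterable[np.ndarray]:
    yield from stack.frames
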