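"""Moving-fish detection in video frames.

The detector combines two cheap motion cues and a fixed morphological
clean-up chain:

1. ``BS``  — frame differencing: a pixel is foreground when its intensity
   changed by more than ``Th`` between consecutive frames,
   ``|l(x', y', t) - l(x', y', t-1)| > Th``.
2. ``MA``  — moving-average background subtraction: the background is an
   exponentially weighted running average of past frames
   (``bg' = alpha * frame + (1 - alpha) * bg``) and a pixel is foreground
   when ``|frame - bg| > Th``.
3. The two masks are fused with a bitwise AND, which suppresses the
   "ghost" a departing fish leaves in either cue alone.
4. Noise cancellation: 15x closing (2x2 kernel), 15x opening (1x1
   kernel), 2x erosion, 10x closing, in that order.
5. Connected components above ``min_blob_area`` yield one centroid per
   moving fish; headings come from nearest-neighbour association with
   the previous frame's centroids.

All coordinates use the image convention: origin top-left, x rightward
(column), y downward (row), 0-based; centroids are real-valued.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSequence",
    "Detection",
    "DetectionSet",
    "DetectorConfig",
    "frame_difference",
    "update_background",
    "moving_average_mask",
    "fuse_masks",
    "denoise",
    "extract_centroids",
    "detect_sequence",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class FrameSequence:
    """Ordered single-channel 8-bit frames with strictly increasing timestamps."""

    frames: np.ndarray  # (T, H, W) uint8
    timestamps: np.ndarray  # (T,) seconds

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim == 4 and self.frames.shape[-1] == 3:
            self.frames = rgb_to_gray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W) after channel conversion")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.frames = self.frames.astype(np.uint8, copy=False)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


def rgb_to_gray(frames: np.ndarray) -> np.ndarray:
    """Luminance conversion (ITU-R BT.601 weights) to a single channel."""
    frames = np.asarray(frames)
    gray = frames[..., 0] * 0.299 + frames[..., 1] * 0.587 + frames[..., 2] * 0.114
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


@dataclass
class Detection:
    """One detected fish: real-valued centroid, blob area, optional heading."""

    x: float
    y: float
    area: float
    heading: float | None = None


@dataclass
class DetectionSet:
    """All detections of one frame."""

    frame_index: int
    timestamp: float
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)

    def centroids(self) -> np.ndarray:
        """(N, 2) array of (x, y) centroids."""
        if not self.detections:
            return np.empty((0, 2))
        return np.array([[d.x, d.y] for d in self.detections])


@dataclass
class DetectorConfig:
    """Detector parameters.

    The morphology chain (close x15 with 2x2, open x15 with 1x1,
    erode x2, close x10 with 2x2) is the fixed noise-cancellation recipe;
    counts and kernels are exposed so the recipe can be re-tuned per
    camera.  Note a 1x1 opening is the identity — it is executed
    literally and logged once; override ``open_kernel`` to make the
    opening effective.
    """

    th: float = 25.0
    alpha: float = 0.05
    close1_iters: int = 15
    open_iters: int = 15
    erode_iters: int = 2
    close2_iters: int = 10
    close_kernel: tuple[int, int] = (2, 2)
    open_kernel: tuple[int, int] = (1, 1)
    erode_kernel: tuple[int, int] = (3, 3)
    min_blob_area: float = 20.0
    heading_gate: float = 15.0  # px; max association distance for headings

    def __post_init__(self) -> None:
        if not 0 <= self.th <= 255:
            raise ValueError(f"th must be in [0, 255], got {self.th}")
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        for name in ("close1_iters", "open_iters", "erode_iters", "close2_iters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("close_kernel", "open_kernel", "erode_kernel"):
            k = getattr(self, name)
            if min(k) < 1:
                raise ValueError(f"{name} must be at least 1x1")
        if self.min_blob_area < 0:
            raise ValueError("min_blob_area must be >= 0")


# ---------------------------------------------------------------------------
# pixel-level operations


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def frame_difference(frame_t: np.ndarray, frame_prev: np.ndarray, th: float) -> np.ndarray:
    """Binary mask of pixels whose intensity changed by more than ``th``.

    Symmetric in its frame arguments (absolute difference).
    """
    frame_t = np.asarray(frame_t)
    frame_prev = np.asarray(frame_prev)
    _check_same_shape(frame_t, frame_prev)
    if not 0 <= th <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {th}")
    diff = np.abs(frame_t.astype(np.int16) - frame_prev.astype(np.int16))
    return diff > th


def update_background(bg: np.ndarray, frame: np.ndarray, alpha: float) -> np.ndarray:
    """Running-average background update ``bg' = alpha*frame + (1-alpha)*bg``."""
    bg = np.asarray(bg, dtype=np.float64)
    frame = np.asarray(frame)
    _check_same_shape(bg, frame)
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * frame.astype(np.float64) + (1.0 - alpha) * bg


def moving_average_mask(frame: np.ndarray, bg: np.ndarray, th: float) -> np.ndarray:
    """Binary mask of pixels deviating from the background model by more than ``th``."""
    frame = np.asarray(frame)
    bg = np.asarray(bg)
    _check_same_shape(frame, bg)
    return np.abs(frame.astype(np.float64) - bg.astype(np.float64)) > th


def fuse_masks(bs: np.ndarray, ma: np.ndarray) -> np.ndarray:
    """Bitwise AND of the two motion masks."""
    bs = np.asarray(bs, dtype=bool)
    ma = np.asarray(ma, dtype=bool)
    _check_same_shape(bs, ma)
    return bs & ma


# ---------------------------------------------------------------------------
# morphology

_warned_identity_opening = False


def _repeat(op, mask: np.ndarray, kernel: np.ndarray, times: int) -> np.ndarray:
    for _ in range(times):
        mask = op(mask, structure=kernel)
    return mask


def denoise(mask: np.ndarray, config: DetectorConfig | None = None) -> np.ndarray:
    """Fixed morphological clean-up chain.

    Applies, in order: closing x ``close1_iters`` (2x2), opening x
    ``open_iters`` (1x1), erosion x ``erode_iters``, closing x
    ``close2_iters`` (2x2).  Executed literally even where a stage is a
    mathematical identity.
    """
    global _warned_identity_opening
    if config is None:
        config = DetectorConfig()
    mask = np.asarray(mask, dtype=bool)
    close_k = np.ones(config.close_kernel, dtype=bool)
    open_k = np.ones(config.open_kernel, dtype=bool)
    erode_k = np.ones(config.erode_kernel, dtype=bool)

    if config.open_kernel == (1, 1) and config.open_iters > 0 and not _warned_identity_opening:
        logger.warning(
            "opening with a 1x1 structuring element is the identity; "
            "set open_kernel to make the opening stage effective"
        )
        _warned_identity_opening = True

    out = _repeat(ndimage.binary_closing, mask, close_k, config.close1_iters)
    out = _repeat(ndimage.binary_opening, out, open_k, config.open_iters)
    out = _repeat(ndimage.binary_erosion, out, erode_k, config.erode_iters)
    out = _repeat(ndimage.binary_closing, out, close_k, config.close2_iters)
    return out


# ---------------------------------------------------------------------------
# centroids and the full pipeline


def extract_centroids(mask: np.ndarray, min_blob_area: float = 0.0) -> list[Detection]:
    """One detection per 8-connected component with area >= ``min_blob_area``.

    The centroid is the arithmetic mean of the component's pixel
    coordinates, returned as (x=column, y=row).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _cc_label(mask, connectivity=2)
    out: list[Detection] = []
    for region in regionprops(labels):
        if region.area < min_blob_area:
            continue
        cy, cx = region.centroid
        out.append(Detection(x=float(cx), y=float(cy), area=float(region.area)))
    return out


def _assign_headings(
    current: list[Detection], previous: DetectionSet | None, gate: float
) -> None:
    """Headings from displacement to the nearest previous-frame detection.

    Greedy nearest-neighbour association; matches beyond ``gate`` pixels
    are rejected and the detection keeps ``heading=None``.
    """
    if previous is None or len(previous) == 0 or not current:
        return
    prev_xy = previous.centroids()
    for det in current:
        d = np.hypot(prev_xy[:, 0] - det.x, prev_xy[:, 1] - det.y)
        j = int(np.argmin(d))
        if d[j] <= gate:
            dx, dy = det.x - prev_xy[j, 0], det.y - prev_xy[j, 1]
            if dx != 0 or dy != 0:
                det.heading = float(np.arctan2(dy, dx))


def detect_sequence(
    frames: FrameSequence, config: DetectorConfig | None = None
) -> list[DetectionSet]:
    """Run the full detector over a frame sequence.

    The background model is initialized to the first frame and updated
    after every frame; detection output starts at frame index 1 (the
    frame difference needs a predecessor).
    """
    if config is None:
        config = DetectorConfig()
    if len(frames) < 2:
        raise ValueError("detect_sequence needs at least 2 frames")

    bg = frames.frames[0].astype(np.float64)
    results: list[DetectionSet] = []
    prev_set: DetectionSet | None = None
    for t in range(1, len(frames)):
        frame = frames.frames[t]
        bs = frame_difference(frame, frames.frames[t - 1], config.th)
        ma = moving_average_mask(frame, bg, config.th)
        fused = fuse_masks(bs, ma)
        cleaned = denoise(fused, config)
        dets = extract_centroids(cleaned, config.min_blob_area)
        _assign_headings(dets, prev_set, config.heading_gate)
        det_set = DetectionSet(
            frame_index=t, timestamp=float(frames.timestamps[t]), detections=dets
        )
        logger.debug("frame %d: %d detections", t, len(dets))
        results.append(det_set)
        prev_set = det_set
        bg = update_background(bg, frame, config.alpha)
    return results
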