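"""Trajectory-marker canvases: the classifier's input representation.

A window of detections (one minute by default) is summarized on a blank
224x224x3 canvas: each detection leaves a short line-segment marker at
its (scaled) position, oriented along the fish's movement direction and
colored by the heading octant.  Position and direction are exactly the
two quantities the downstream pattern classifier needs; the fixed canvas
size matches the network's input layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

from .detection import DetectionSet

__all__ = [
    "CANVAS_SHAPE",
    "CanvasConfig",
    "TrajectoryImage",
    "render_trajectory_image",
    "render_window",
    "window_detections",
    "OCTANT_COLORS",
    "NO_HEADING_COLOR",
    "heading_octant",
]

CANVAS_SHAPE = (224, 224, 3)

#: 8-octant heading colormap (index 0 = headings in [-pi, -3pi/4)).
OCTANT_COLORS: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0),
    (255, 128, 0),
    (255, 255, 0),
    (0, 255, 0),
    (0, 255, 255),
    (0, 0, 255),
    (128, 0, 255),
    (255, 0, 255),
)

#: Reserved marker color for detections without a heading (drawn as dots).
NO_HEADING_COLOR: tuple[int, int, int] = (255, 255, 255)


def heading_octant(heading: float) -> int:
    """Octant index 0-7 for a heading in radians (any branch)."""
    wrapped = (heading + np.pi) % (2 * np.pi)  # [0, 2pi)
    return int(wrapped // (np.pi / 4)) % 8


@dataclass
class CanvasConfig:
    """Canvas parameters.

    ``window_seconds`` is the time span summarized per canvas (frames are
    accumulated every minute by default); ``frame_stride`` subsamples the
    frames contributing markers (1 = every frame).
    """

    window_seconds: float = 60.0
    marker_length: int = 9
    background_color: tuple[int, int, int] = (0, 0, 0)
    frame_stride: int = 1

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be > 0")
        if self.marker_length < 1:
            raise ValueError("marker_length must be >= 1")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


@dataclass
class TrajectoryImage:
    """A rendered marker canvas plus its time window."""

    pixels: np.ndarray  # (224, 224, 3) uint8
    window_start: float
    window_end: float

    def __post_init__(self) -> None:
        if self.pixels.shape != CANVAS_SHAPE:
            raise ValueError(f"canvas must have shape {CANVAS_SHAPE}")


def _arena_to_canvas(arena: tuple[int, int]) -> tuple[float, float, float]:
    """Aspect-preserving scale + letterbox offsets mapping arena px to canvas px."""
    w, h = arena
    if w <= 0 or h <= 0:
        raise ValueError("arena dimensions must be > 0")
    s = min(CANVAS_SHAPE[1] / w, CANVAS_SHAPE[0] / h)
    ox = (CANVAS_SHAPE[1] - s * w) / 2.0
    oy = (CANVAS_SHAPE[0] - s * h) / 2.0
    return s, ox, oy


def render_trajectory_image(
    detections: list[DetectionSet],
    config: CanvasConfig | None = None,
    arena: tuple[int, int] = (320, 240),
) -> np.ndarray:
    """Draw one marker per detection on a blank canvas.

    Markers are aliasing-free line segments of ``marker_length`` px
    centered at the scaled detection position, angle = heading, color by
    heading octant.  Detections without a heading become single-pixel
    dots in the reserved color.  Output is always 224x224x3 uint8.
    """
    if config is None:
        config = CanvasConfig()
    s, ox, oy = _arena_to_canvas(arena)
    canvas = np.empty(CANVAS_SHAPE, dtype=np.uint8)
    canvas[:] = config.background_color
    half = (config.marker_length - 1) / 2.0
    hmax, wmax = CANVAS_SHAPE[0] - 1, CANVAS_SHAPE[1] - 1

    for det_set in detections[:: config.frame_stride]:
        for det in det_set.detections:
            cx, cy = ox + s * det.x, oy + s * det.y
            if det.heading is None:
                r = int(np.clip(round(cy), 0, hmax))
                c = int(np.clip(round(cx), 0, wmax))
                canvas[r, c] = NO_HEADING_COLOR
                continue
            dx, dy = np.cos(det.heading), np.sin(det.heading)
            r0 = int(np.clip(round(cy - half * dy), 0, hmax))
            c0 = int(np.clip(round(cx - half * dx), 0, wmax))
            r1 = int(np.clip(round(cy + half * dy), 0, hmax))
            c1 = int(np.clip(round(cx + half * dx), 0, wmax))
            rr, cc = _draw_line(r0, c0, r1, c1)
            canvas[rr, cc] = OCTANT_COLORS[heading_octant(det.heading)]
    return canvas


def render_window(
    window: list[DetectionSet],
    config: CanvasConfig | None = None,
    arena: tuple[int, int] = (320, 240),
) -> TrajectoryImage:
    """Render a detection window and keep its time span."""
    if config is None:
        config = CanvasConfig()
    pixels = render_trajectory_image(window, config, arena)
    if window:
        t0 = min(d.timestamp for d in window)
        k = np.floor(t0 / config.window_seconds)
        start = float(k * config.window_seconds)
    else:
        start = 0.0
    return TrajectoryImage(pixels=pixels, window_start=start,
                           window_end=start + config.window_seconds)


def window_detections(
    stream: list[DetectionSet], window_seconds: float
) -> list[list[DetectionSet]]:
    """Partition a detection stream into consecutive half-open time windows.

    Window ``k`` covers ``[k*w, (k+1)*w)``; a timestamp exactly on a
    boundary belongs to the *later* window.  Returns one list per window
    from the first to the last occupied window (intermediate empty
    windows are preserved so window indices stay aligned with time).
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be > 0")
    if not stream:
        return []
    ts = [d.timestamp for d in stream]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("detection timestamps must be monotone nondecreasing")
    k_min = int(np.floor(ts[0] / window_seconds))
    k_max = int(np.floor(ts[-1] / window_seconds))
    windows: list[list[DetectionSet]] = [[] for _ in range(k_max - k_min + 1)]
    for det_set in stream:
        k = int(np.floor(det_set.timestamp / window_seconds))
        windows[k - k_min].append(det_set)
    return windows
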