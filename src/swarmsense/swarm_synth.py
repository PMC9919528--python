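"""Synthetic fish-swarm trajectories, rendered tank video, and labeled datasets.

Real recordings of the study tank are not available, so every downstream
stage (detector, trajectory canvas, pattern classifier) is exercised on
synthetic data from this module.  The generator emulates a top-down view
of a bounded tank of ~10 carp under four swarm regimes:

* ``FOLLOWING`` (pattern 1) — single-file schooling: a leader wanders and
  each fish steers toward its predecessor.
* ``PARALLEL`` (pattern 2)  — polarized schooling: the group shares one
  heading with small per-fish jitter.
* ``SHOAL`` (pattern 3)     — loose aggregation: independent persistent
  random walks with weak cohesion, headings unpolarized.
* ``TORNADO`` (pattern 4)   — circulation: the group orbits its centroid
  at a regulated radius with a fixed rotation sense.

The update rules are this package's own (boids-style presets); no
quantitative motion model of the original fish exists to copy.  Rendered
frames add the nuisance signals that plague real underwater footage:
rising air bubbles, a swirling local vortex distortion, and illumination
drift.

All generators are pure functions of (config, seed).  Positions are kept
inside the arena by reflecting at the walls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .detection import Detection, DetectionSet, FrameSequence

__all__ = [
    "SwarmPattern",
    "SwarmSimConfig",
    "SwarmTrajectory",
    "NoiseConfig",
    "simulate_swarm",
    "render_frames",
    "detections_from_trajectory",
    "make_pattern_dataset",
]


class SwarmPattern(enum.IntEnum):
    """The four-pattern corpus, with stable integer codes 1-4."""

    FOLLOWING = 1
    PARALLEL = 2
    SHOAL = 3
    TORNADO = 4


def wrap_angle(a):
    """Wrap angles to [-pi, pi)."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


@dataclass
class SwarmSimConfig:
    """Swarm simulation parameters.

    Defaults emulate the study tank scaled to pixels: 10 fish in a
    320x240 px arena, 200 steps of 0.5 s, swimming ~3 px/step.  The
    boids gains are dimensionless steering weights used by the pattern
    presets.  ``base_heading`` (radians) pins the initial/shared travel
    direction of the polarized patterns; ``None`` draws it from the seed.
    """

    n_fish: int = 10
    arena: tuple[int, int] = (320, 240)  # (width, height) px
    steps: int = 200
    dt: float = 0.5
    speed: float = 3.0  # px / step
    cohesion: float = 0.05
    alignment: float = 0.5
    separation: float = 1.0
    noise_sd: float = 0.3  # px / step positional jitter
    heading_jitter: float = 0.05  # rad, per-fish jitter in polarized patterns
    base_heading: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 0:
            raise ValueError("n_fish must be >= 0")
        if min(self.arena) <= 0:
            raise ValueError("arena dimensions must be > 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        # motion sub-stream; noise rendering uses its own stream
        return np.random.default_rng(np.random.SeedSequence([self.seed, 0]))


@dataclass
class SwarmTrajectory:
    """Per-fish, per-step positions (px) and headings (rad, [-pi, pi))."""

    positions: np.ndarray  # (n_fish, steps, 2) as (x, y)
    headings: np.ndarray  # (n_fish, steps)
    pattern: SwarmPattern
    arena: tuple[int, int]
    dt: float

    @property
    def n_fish(self) -> int:
        return self.positions.shape[0]

    @property
    def steps(self) -> int:
        return self.positions.shape[1]


@dataclass
class NoiseConfig:
    """Underwater nuisance signals added to rendered frames.

    * bubbles — transient bright discs rising toward row 0, spawned at
      ``bubble_rate`` expected bubbles per frame;
    * vortex  — a drifting local sinusoidal pixel displacement of
      amplitude ``vortex_amplitude`` px;
    * drift   — an additive intensity ramp of ``illumination_drift``
      units per frame.
    """

    bubble_rate: float = 1.0
    vortex_amplitude: float = 2.0
    illumination_drift: float = 0.2
    bubble_radius: float = 5.0
    bubble_speed: float = 4.0  # px / frame upward
    vortex_radius: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bubble_rate", "vortex_amplitude", "illumination_drift",
                     "bubble_radius", "bubble_speed", "vortex_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseConfig":
        """All nuisance signals off."""
        return cls(bubble_rate=0.0, vortex_amplitude=0.0,
                   illumination_drift=0.0, seed=seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 1]))


# ---------------------------------------------------------------------------
# swarm simulation


def _clip_positions(pos: np.ndarray, arena: tuple[int, int], margin: float) -> np.ndarray:
    w, h = arena
    return np.clip(pos, [margin, margin], [w - 1 - margin, h - 1 - margin])


def _init_group_positions(
    rng: np.random.Generator, n: int, arena: tuple[int, int], spacing: float
) -> np.ndarray:
    """Jittered grid centered in the arena; keeps fish initially separated."""
    if n == 0:
        return np.empty((0, 2))
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    gx, gy = np.meshgrid(np.arange(cols), np.arange(rows))
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)[:n].astype(float) * spacing
    pts -= pts.mean(axis=0)
    center = np.array(arena, dtype=float) / 2.0
    pts += center + rng.normal(0, spacing * 0.1, size=pts.shape)
    return _clip_positions(pts, arena, margin=2.0)


def _simulate_parallel(cfg: SwarmSimConfig, rng: np.random.Generator):
    n, (w, h) = cfg.n_fish, cfg.arena
    phi = cfg.base_heading if cfg.base_heading is not None else rng.uniform(-np.pi, np.pi)
    # ~1.5 body lengths between lanes: polarized schools keep clear spacing
    pos = _init_group_positions(rng, n, cfg.arena, spacing=10 * cfg.speed)
    P = np.empty((n, cfg.steps, 2))
    H = np.empty((n, cfg.steps))
    margin = 2.0
    for t in range(cfg.steps):
        jitter = rng.normal(0, cfg.heading_jitter, size=n)
        # synchronized group reflection: flip the shared heading when any
        # member would exit, so the school stays polarized at the walls
        step_vec = cfg.speed * np.stack([np.cos(phi + jitter), np.sin(phi + jitter)], axis=-1)
        nxt = pos + step_vec
        if n and (nxt[:, 0].min() < margin or nxt[:, 0].max() > w - 1 - margin):
            phi = wrap_angle(np.pi - phi)
        if n and (nxt[:, 1].min() < margin or nxt[:, 1].max() > h - 1 - margin):
            phi = wrap_angle(-phi)
        headings = wrap_angle(phi + jitter)
        pos = pos + cfg.speed * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
        pos = pos + rng.normal(0, cfg.noise_sd, size=pos.shape)
        pos = _clip_positions(pos, cfg.arena, margin)
        P[:, t] = pos
        H[:, t] = headings
    return P, H


def _reflect_heading(phi: float, pos: np.ndarray, arena, margin: float, speed: float) -> float:
    """Flip heading components that would take ``pos`` out of the arena."""
    w, h = arena
    nxt = pos + speed * np.array([np.cos(phi), np.sin(phi)])
    if nxt[0] < margin or nxt[0] > w - 1 - margin:
        phi = np.pi - phi
    if nxt[1] < margin or nxt[1] > h - 1 - margin:
        phi = -phi
    return float(wrap_angle(phi))


def _simulate_following(cfg: SwarmSimConfig, rng: np.random.Generator):
    n = cfg.n_fish
    gap = 2.0 * cfg.speed  # target spacing between chain members
    margin = 2.0
    phi = cfg.base_heading if cfg.base_heading is not None else rng.uniform(-np.pi, np.pi)
    center = np.array(cfg.arena, dtype=float) / 2.0
    # chain laid out behind the leader
    idx = np.arange(n)[:, None]
    pos = center - idx * gap * np.array([np.cos(phi), np.sin(phi)])
    pos = _clip_positions(pos, cfg.arena, margin)
    P = np.empty((n, cfg.steps, 2))
    H = np.empty((n, cfg.steps))
    headings = np.full(n, wrap_angle(phi))
    for t in range(cfg.steps):
        if n:
            phi = wrap_angle(phi + rng.normal(0, 0.08))
            phi = _reflect_heading(phi, pos[0], cfg.arena, margin + cfg.speed, cfg.speed)
            headings[0] = phi
            pos[0] += cfg.speed * np.array([np.cos(phi), np.sin(phi)])
        for i in range(1, n):
            to_pred = pos[i - 1] - pos[i]
            dist = np.hypot(*to_pred)
            headings[i] = np.arctan2(to_pred[1], to_pred[0]) if dist > 1e-9 else headings[i]
            # speed up when lagging, ease off when crowding the predecessor
            v = cfg.speed * np.clip(dist / gap, 0.3, 1.5)
            pos[i] += v * np.array([np.cos(headings[i]), np.sin(headings[i])])
        pos += rng.normal(0, cfg.noise_sd, size=pos.shape)
        pos = _clip_positions(pos, cfg.arena, margin)
        P[:, t] = pos
        H[:, t] = wrap_angle(headings)
    return P, H


def _simulate_shoal(cfg: SwarmSimConfig, rng: np.random.Generator):
    n, (w, h) = cfg.n_fish, cfg.arena
    margin = 2.0
    pos = np.stack(
        [rng.uniform(margin, w - 1 - margin, size=n),
         rng.uniform(margin, h - 1 - margin, size=n)], axis=-1,
    ) if n else np.empty((0, 2))
    headings = rng.uniform(-np.pi, np.pi, size=n)
    P = np.empty((n, cfg.steps, 2))
    H = np.empty((n, cfg.steps))
    for t in range(cfg.steps):
        headings = headings + rng.normal(0, 0.5, size=n)
        if n:
            centroid = pos.mean(axis=0)
            to_c = centroid - pos
            far = np.hypot(to_c[:, 0], to_c[:, 1]) > 0.4 * min(w, h)
            # weak cohesion: distant stragglers drift back toward the group
            pull = np.arctan2(to_c[:, 1], to_c[:, 0])
            headings = np.where(
                far, headings + cfg.cohesion * wrap_angle(pull - headings), headings
            )
        for i in range(n):
            headings[i] = _reflect_heading(headings[i], pos[i], cfg.arena, margin, cfg.speed)
        headings = wrap_angle(headings)
        pos = pos + cfg.speed * np.stack([np.cos(headings), np.sin(headings)], axis=-1)
        pos = pos + rng.normal(0, cfg.noise_sd, size=pos.shape)
        pos = _clip_positions(pos, cfg.arena, margin)
        P[:, t] = pos
        H[:, t] = headings
    return P, H


def _simulate_tornado(cfg: SwarmSimConfig, rng: np.random.Generator):
    n, (w, h) = cfg.n_fish, cfg.arena
    center = np.array([w, h], dtype=float) / 2.0
    radius0 = 0.25 * min(w, h)
    sense = 1.0 if rng.random() < 0.5 else -1.0  # rotation direction
    omega = sense * cfg.speed / radius0  # rad / step
    ang = rng.uniform(-np.pi, np.pi) + np.linspace(0, 2 * np.pi, n, endpoint=False)
    rad = radius0 * rng.uniform(0.9, 1.1, size=n)
    P = np.empty((n, cfg.steps, 2))
    H = np.empty((n, cfg.steps))
    for t in range(cfg.steps):
        ang = ang + omega + rng.normal(0, cfg.noise_sd / radius0, size=n)
        # radius regulation keeps the ring tight about the group centroid
        rad = rad + 0.1 * (radius0 - rad) + rng.normal(0, cfg.noise_sd, size=n)
        pos = center + rad[:, None] * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        pos = _clip_positions(pos, cfg.arena, 2.0)
        P[:, t] = pos
        # heading tangent to the orbit, in the direction of travel
        H[:, t] = wrap_angle(ang + sense * np.pi / 2)
    return P, H


_SIMULATORS = {
    SwarmPattern.FOLLOWING: _simulate_following,
    SwarmPattern.PARALLEL: _simulate_parallel,
    SwarmPattern.SHOAL: _simulate_shoal,
    SwarmPattern.TORNADO: _simulate_tornado,
}


def simulate_swarm(pattern: SwarmPattern, config: SwarmSimConfig | None = None) -> SwarmTrajectory:
    """Simulate one swarm under the given pattern regime.

    Deterministic given (pattern, config, config.seed).
    """
    if config is None:
        config = SwarmSimConfig()
    try:
        pattern = SwarmPattern(pattern)
    except ValueError as err:
        raise ValueError(f"unknown swarm pattern: {pattern!r}") from err
    rng = config.rng()
    positions, headings = _SIMULATORS[pattern](config, rng)
    return SwarmTrajectory(
        positions=positions, headings=wrap_angle(headings),
        pattern=pattern, arena=config.arena, dt=config.dt,
    )


# ---------------------------------------------------------------------------
# frame rendering


_FISH_EDGE_INTENSITY = 120.0
_FISH_SHADE_RANGE = 70.0
_FISH_TEXTURE_AMP = 55.0
_FISH_TEXTURE_WAVELENGTH = 7.0  # px along the body axis


def _draw_fish(frame: np.ndarray, x: float, y: float, heading: float,
               radius: float, texture_phase: float = 0.0) -> None:
    """Filled 2:1 ellipse along ``heading`` with shading and body texture.

    The interior carries a banded texture fixed in body coordinates
    (emulating scale/fin markings): a flat silhouette would defeat frame
    differencing, because a fish sliding along its own major axis barely
    changes any interior pixel.
    """
    a, b = 2.0 * radius, radius  # semi-major (along heading), semi-minor
    h, w = frame.shape
    x0, x1 = int(max(0, np.floor(x - a))), int(min(w, np.ceil(x + a) + 1))
    y0, y1 = int(max(0, np.floor(y - a))), int(min(h, np.ceil(y + a) + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    xi = dx * np.cos(heading) + dy * np.sin(heading)
    eta = -dx * np.sin(heading) + dy * np.cos(heading)
    rho2 = (xi / a) ** 2 + (eta / b) ** 2
    inside = rho2 <= 1.0
    # bands keep full amplitude out to the silhouette so motion changes
    # interior pixels everywhere, as real scale/fin texture does
    bands = _FISH_TEXTURE_AMP * np.sin(
        2 * np.pi * xi / _FISH_TEXTURE_WAVELENGTH + texture_phase
    )
    shade = _FISH_EDGE_INTENSITY + _FISH_SHADE_RANGE * (1.0 - rho2) + bands
    patch = frame[y0:y1, x0:x1]
    patch[inside] = np.maximum(patch[inside], shade[inside])


def _draw_disc(frame: np.ndarray, x: float, y: float, radius: float, intensity: float) -> None:
    h, w = frame.shape
    x0, x1 = int(max(0, np.floor(x - radius))), int(min(w, np.ceil(x + radius) + 1))
    y0, y1 = int(max(0, np.floor(y - radius))), int(min(h, np.ceil(y + radius) + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    patch = frame[y0:y1, x0:x1]
    patch[inside] = np.maximum(patch[inside], intensity)


def _apply_vortex(frame: np.ndarray, cx: float, cy: float, radius: float,
                  amplitude: float, phase: float) -> np.ndarray:
    """Local swirl: pixels inside the vortex disc are resampled along a
    sinusoidally modulated tangential displacement."""
    h, w = frame.shape
    x0, x1 = int(max(0, cx - radius)), int(min(w, cx + radius + 1))
    y0, y1 = int(max(0, cy - radius)), int(min(h, cy + radius + 1))
    if x1 - x0 < 3 or y1 - y0 < 3:
        return frame
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    falloff = np.clip(1.0 - r / radius, 0.0, 1.0)
    swirl = amplitude * falloff * np.sin(2 * np.pi * r / max(radius, 1.0) + phase)
    with np.errstate(invalid="ignore", divide="ignore"):
        tx, ty = np.where(r > 0, -dy / r, 0.0), np.where(r > 0, dx / r, 0.0)
    src_y = np.clip(yy + swirl * ty, 0, h - 1)
    src_x = np.clip(xx + swirl * tx, 0, w - 1)
    warped = ndimage.map_coordinates(frame.astype(float), [src_y, src_x], order=1)
    out = frame.astype(float)
    out[y0:y1, x0:x1] = warped
    return out


def render_frames(
    traj: SwarmTrajectory,
    noise: NoiseConfig | None = None,
    fish_radius: float = 5.0,
) -> tuple[FrameSequence, list[DetectionSet]]:
    """Render one frame per trajectory step plus per-frame ground truth.

    Fish are drawn as filled 2:1 ellipses oriented along their heading;
    nuisance noise is applied after the fish.  The returned ground truth
    lists the true centroids/headings (areas are the analytic ellipse
    area), so detector accuracy can be scored exactly.
    """
    if noise is None:
        noise = NoiseConfig.none()
    if fish_radius < 1:
        raise ValueError("fish_radius must be >= 1")
    if 4 * fish_radius > min(traj.arena):
        raise ValueError("fish_radius too large for the arena")
    w, h = traj.arena
    rng = noise.rng()
    frames = np.empty((traj.steps, h, w), dtype=np.uint8)
    truth: list[DetectionSet] = []
    bubbles: list[list[float]] = []  # [x, y, radius]
    vortex_pos = np.array([rng.uniform(0, w), rng.uniform(0, h)])

    for t in range(traj.steps):
        frame = np.zeros((h, w), dtype=float)
        dets: list[Detection] = []
        for i in range(traj.n_fish):
            x, y = traj.positions[i, t]
            heading = float(traj.headings[i, t])
            _draw_fish(frame, x, y, heading, fish_radius, texture_phase=1.7 * i)
            dets.append(Detection(
                x=float(x), y=float(y),
                area=float(np.pi * 2 * fish_radius * fish_radius),
                heading=heading,
            ))

        # --- nuisance signals, applied after the fish ---
        if noise.bubble_rate > 0:
            for _ in range(rng.poisson(noise.bubble_rate)):
                bubbles.append([rng.uniform(0, w), h - 1.0,
                                noise.bubble_radius * rng.uniform(0.7, 1.3)])
            for bub in bubbles:
                bub[1] -= noise.bubble_speed
                bub[0] += rng.normal(0, 0.5)
                _draw_disc(frame, bub[0], bub[1], bub[2], 255.0)
            bubbles = [b for b in bubbles if b[1] > -b[2]]
        if noise.vortex_amplitude > 0:
            vortex_pos += rng.normal(0, 2.0, size=2)
            vortex_pos = np.clip(vortex_pos, 0, [w - 1, h - 1])
            frame = _apply_vortex(frame, vortex_pos[0], vortex_pos[1],
                                  noise.vortex_radius, noise.vortex_amplitude,
                                  phase=0.4 * t)
        if noise.illumination_drift > 0:
            frame = frame + noise.illumination_drift * t

        frames[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        truth.append(DetectionSet(frame_index=t, timestamp=t * traj.dt, detections=dets))

    seq = FrameSequence(frames=frames, timestamps=np.arange(traj.steps) * traj.dt)
    return seq, truth


def detections_from_trajectory(traj: SwarmTrajectory) -> list[DetectionSet]:
    """Ground-truth detections straight from a trajectory (no rendering)."""
    out = []
    for t in range(traj.steps):
        dets = [
            Detection(x=float(traj.positions[i, t, 0]), y=float(traj.positions[i, t, 1]),
                      area=0.0, heading=float(traj.headings[i, t]))
            for i in range(traj.n_fish)
        ]
        out.append(DetectionSet(frame_index=t, timestamp=t * traj.dt, detections=dets))
    return out


# ---------------------------------------------------------------------------
# labeled pattern dataset


def make_pattern_dataset(
    n_per_class: int,
    seed: int = 0,
    sim_config: SwarmSimConfig | None = None,
    canvas_config=None,
):
    """Balanced labeled trajectory-image dataset, 4 x ``n_per_class`` images.

    Each image is produced by ``simulate_swarm`` (fresh child seed per
    sample) followed by the trajectory-canvas renderer.  Returns a
    ``LabeledDataset`` of 224x224x3 uint8 images.
    """
    from .pattern_classifier import LabeledDataset
    from .trajectory_canvas import CanvasConfig, render_trajectory_image

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = sim_config if sim_config is not None else SwarmSimConfig(steps=150)
    canvas = canvas_config if canvas_config is not None else CanvasConfig()
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(4 * n_per_class)

    images, labels = [], []
    k = 0
    for pattern in SwarmPattern:
        for _ in range(n_per_class):
            cfg = SwarmSimConfig(
                n_fish=base.n_fish, arena=base.arena, steps=base.steps,
                dt=base.dt, speed=base.speed, cohesion=base.cohesion,
                alignment=base.alignment, separation=base.separation,
                noise_sd=base.noise_sd, heading_jitter=base.heading_jitter,
                base_heading=base.base_heading,
                seed=int(child_seeds[k] % (2**31)),
            )
            k += 1
            traj = simulate_swarm(pattern, cfg)
            img = render_trajectory_image(
                detections_from_trajectory(traj), canvas, arena=cfg.arena
            )
            images.append(img)
            labels.append(pattern)
    return LabeledDataset(images=np.stack(images), labels=labels)
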