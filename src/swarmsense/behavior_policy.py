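"""Food-drop behavior policy for the robotic fish.

Maps an observed swarm pattern to one of four food-drop maneuvers
(S-shape, C-shape, O-shape, straight), enforces the daily dosing cap
(dropping food too often degrades water quality), and analyses observed
response tables.

The mapped response sets encode which drop patterns each swarm pattern
was observed to respond to:

* FOLLOWING  -> all four drop patterns
* PARALLEL   -> C-shape and straight
* SHOAL      -> O-shape only
* TORNADO    -> O-shape and C-shape

Per-pattern interest windows (seconds until the school loses interest):
straight 22, S-shape 28, C-shape 32, O-shape 19.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .swarm_synth import SwarmPattern

__all__ = [
    "FoodDropPattern",
    "PolicyConfig",
    "RESPONSE_SETS",
    "select_food_pattern",
    "response_percentages",
    "interest_decay_flag",
    "FoodDropScheduler",
]


class FoodDropPattern(enum.Enum):
    S_SHAPE = "s_shape"
    C_SHAPE = "c_shape"
    O_SHAPE = "o_shape"
    STRAIGHT = "straight"


#: Drop patterns each observed swarm pattern responds to (mapped mode).
RESPONSE_SETS: dict[SwarmPattern, tuple[FoodDropPattern, ...]] = {
    SwarmPattern.FOLLOWING: (
        FoodDropPattern.S_SHAPE,
        FoodDropPattern.C_SHAPE,
        FoodDropPattern.O_SHAPE,
        FoodDropPattern.STRAIGHT,
    ),
    SwarmPattern.PARALLEL: (FoodDropPattern.C_SHAPE, FoodDropPattern.STRAIGHT),
    SwarmPattern.SHOAL: (FoodDropPattern.O_SHAPE,),
    SwarmPattern.TORNADO: (FoodDropPattern.O_SHAPE, FoodDropPattern.C_SHAPE),
}

_DEFAULT_INTEREST_WINDOWS = {
    FoodDropPattern.STRAIGHT: 22.0,
    FoodDropPattern.S_SHAPE: 28.0,
    FoodDropPattern.C_SHAPE: 32.0,
    FoodDropPattern.O_SHAPE: 19.0,
}


@dataclass
class PolicyConfig:
    """Feeding-policy parameters.

    mode
        ``"mapped"`` draws uniformly from the observed pattern's response
        set; ``"random"`` draws uniformly over all four drop patterns
        (the simple random assignment used during data collection).
    max_drops_per_day
        Hard dosing cap; at most this many drops in any rolling 24 h.
    interest_windows
        Seconds after a drop until fish interest lapses, per pattern.
    """

    mode: str = "mapped"
    max_drops_per_day: int = 5
    interest_windows: dict[FoodDropPattern, float] = field(
        default_factory=lambda: dict(_DEFAULT_INTEREST_WINDOWS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mapped", "random"):
            raise ValueError(f"mode must be 'mapped' or 'random', got {self.mode!r}")
        if self.max_drops_per_day < 0:
            raise ValueError("max_drops_per_day must be >= 0")
        for pat, w in self.interest_windows.items():
            if w <= 0:
                raise ValueError(f"interest window for {pat} must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def select_food_pattern(
    observed: SwarmPattern,
    config: PolicyConfig,
    drops_today: int,
    human_present: bool,
    rng: np.random.Generator | None = None,
) -> FoodDropPattern | None:
    """Choose a food-drop pattern, or ``None`` when dropping is not allowed.

    Returns ``None`` when the daily cap is reached or no human is present
    (the robot only performs for an audience).  Pass a ``rng`` to draw
    several selections from one seeded stream; otherwise the config seed
    produces a fresh stream (deterministic per call).
    """
    if not isinstance(observed, SwarmPattern):
        raise ValueError(f"unknown swarm pattern: {observed!r}")
    if drops_today < 0:
        raise ValueError("drops_today must be >= 0")
    if drops_today >= config.max_drops_per_day or not human_present:
        return None
    if rng is None:
        rng = config.rng()
    if config.mode == "random":
        options = tuple(FoodDropPattern)
    else:
        options = RESPONSE_SETS[observed]
    return options[int(rng.integers(len(options)))]


def response_percentages(table: np.ndarray) -> np.ndarray:
    """Row-normalized percentages of a swarm-pattern x drop-pattern table.

    Each cell becomes ``count / row_total * 100``.  A zero row is
    undefined: it is returned as NaN and flagged with a warning rather
    than silently zeroed.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("response table must be 2-D")
    if (table < 0).any():
        raise ValueError("response table counts must be nonnegative")
    row_totals = table.sum(axis=1)
    zero_rows = np.flatnonzero(row_totals == 0)
    if zero_rows.size:
        warnings.warn(
            f"rows {zero_rows.tolist()} have zero total; percentages undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = table / row_totals[:, None] * 100.0
    out[zero_rows, :] = np.nan
    return out


def interest_decay_flag(
    elapsed: float, pattern: FoodDropPattern, config: PolicyConfig
) -> bool:
    """True iff fish interest has lapsed: ``elapsed`` strictly exceeds the
    pattern's maximum response time."""
    if elapsed < 0:
        raise ValueError("elapsed time must be >= 0")
    return elapsed > config.interest_windows[pattern]


class FoodDropScheduler:
    """Tracks drop times and enforces the cap over a rolling 24 h window.

    The "day" is not a calendar boundary: a drop is allowed only if fewer
    than ``max_drops_per_day`` drops happened in the preceding 24 hours,
    which is the conservative reading of a per-day cap.
    """

    DAY_SECONDS = 86400.0

    def __init__(self, config: PolicyConfig):
        self.config = config
        self._drop_times: list[float] = []
        self._rng = config.rng()

    @property
    def drop_times(self) -> list[float]:
        return list(self._drop_times)

    def drops_in_window(self, now: float) -> int:
        return sum(1 for t in self._drop_times if now - self.DAY_SECONDS < t <= now)

    def request_drop(
        self, now: float, observed: SwarmPattern, human_present: bool
    ) -> FoodDropPattern | None:
        """Attempt a drop at time ``now`` (seconds); records it if granted."""
        if self._drop_times and now < self._drop_times[-1]:
            raise ValueError("drop requests must be in nondecreasing time order")
        chosen = select_food_pattern(
            observed,
            self.config,
            drops_today=self.drops_in_window(now),
            human_present=human_present,
            rng=self._rng,
        )
        if chosen is not None:
            self._drop_times.append(now)
        return chosen
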