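"""Task and agent configuration objects.

All lengths are in Unreal units (U.u.); the default arena of radius
5000 U.u. corresponds to about 16 virtual meters, so one virtual meter
is 5000/16 = 312.5 U.u.  Configs validate themselves on construction and
round-trip through YAML for reproducible study definitions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "ArenaConfig",
    "NavigatorParams",
    "YMazeConfig",
    "TownConfig",
    "default_target_positions",
    "config_to_yaml",
    "config_from_yaml",
]


def default_target_positions(radius: float = 5000.0, n: int = 8, *, seed: int = 7
                             ) -> list[tuple[float, float]]:
    """Eight fixed object locations sampling central through peripheral radii.

    The locations are deterministic (a fixed internal seed): every simulated
    participant is tested on the same set, as in the task design, with radii
    spread from near-center to near-bank.
    """
    rng = np.random.default_rng(seed)
    radii = np.linspace(0.12, 0.85, n) * radius
    angles = rng.permutation(np.arange(n)) * (2 * math.pi / n) + rng.uniform(0, 2 * math.pi)
    return [(float(r * math.cos(a)), float(r * math.sin(a)))
            for r, a in zip(radii, angles)]


@dataclass(frozen=True)
class ArenaConfig:
    """Open circular arena with graded drop-off feedback.

    ``feedback_thresholds`` are the four drop-error cut points separating the
    five feedback grades; the outer cuts (700 and 4500 U.u.) follow the task
    description, the interior cuts are an equally spaced convention.
    """

    radius: float = 5000.0
    uu_per_meter: float = 5000.0 / 16.0
    n_targets: int = 8
    target_positions: tuple[tuple[float, float], ...] = ()
    sample_rate: float = 10.0        # Hz; logging rate is a free parameter
    feedback_thresholds: tuple[float, ...] = (700.0, 700 + 3800 / 3, 700 + 2 * 3800 / 3, 4500.0)
    session_blocks: int = 6
    block_duration: float = 600.0    # s
    start_radius: float = 879.0      # initial placement distance from center

    def __post_init__(self):
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"radius must be positive and finite, got {self.radius}")
        if self.sample_rate <= 0 or self.block_duration <= 0 or self.session_blocks < 1:
            raise ValueError("sample_rate, block_duration and session_blocks must be positive")
        if not self.target_positions:
            object.__setattr__(
                self, "target_positions",
                tuple(default_target_positions(self.radius, self.n_targets)))
        if len(self.target_positions) != self.n_targets:
            raise ValueError("target_positions length must equal n_targets")
        for p in self.target_positions:
            if not all(math.isfinite(c) for c in p):
                raise ValueError(f"non-finite target position {p}")
            if math.hypot(*p) >= self.radius:
                raise ValueError(f"target {p} not strictly inside arena of radius {self.radius}")
        cuts = self.feedback_thresholds
        if len(cuts) != 4 or any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("feedback_thresholds must be 4 strictly increasing cut points")
        if not 0 < self.start_radius < self.radius:
            raise ValueError("start_radius must lie strictly inside the arena")

    @property
    def session_duration(self) -> float:
        return self.session_blocks * self.block_duration


@dataclass(frozen=True)
class NavigatorParams:
    """Behavioral parameters of one synthetic navigator.

    ``thigmotaxis_bias`` in [0, 1] pulls travel toward the ring of radius
    ``bias * R`` (0 = beeline navigation, 1 = wall hugging).
    ``memory_noise_sd`` is the SD (U.u.) of isotropic Gaussian error on the
    remembered object locations, the generative knob behind drop error.
    """

    strategy: str = "allocentric"    # allocentric | egocentric | mixed
    memory_noise_sd: float = 600.0
    thigmotaxis_bias: float = 0.3
    speed: float = 650.0             # U.u./s (~2 virtual m/s)
    idle_prob: float = 0.004         # per-sample probability of pausing
    idle_dwell: float = 1.5          # mean pause duration, s
    heading_jitter_sd: float = 6.0   # degrees per step
    notice_change_prob: float = 0.1  # P(egocentric agent reports noticing cue change)
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("allocentric", "egocentric", "mixed"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.thigmotaxis_bias <= 1.0:
            raise ValueError("thigmotaxis_bias must be in [0, 1]")
        if not (math.isfinite(self.speed) and self.speed > 0):
            raise ValueError("speed must be positive and finite")
        if self.memory_noise_sd < 0 or not math.isfinite(self.memory_noise_sd):
            raise ValueError("memory_noise_sd must be >= 0 and finite")
        if not 0.0 <= self.idle_prob <= 1.0 or not 0.0 <= self.notice_change_prob <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class YMazeConfig:
    """Three-arm maze probing allocentric vs egocentric strategy.

    Arms radiate at 120 deg; training starts from a fixed arm, the probe
    starts from the third arm to dissociate repeating a body turn from
    heading to the cue-defined target arm.
    """

    n_arms: int = 3
    arm_angle: float = 120.0
    training_start_arm: int = 0
    target_arm: int = 1
    probe_start_arm: int = 2
    criterion: int = 5               # consecutive correct trials ending training

    def __post_init__(self):
        if self.n_arms != 3:
            raise ValueError("the maze has exactly 3 arms")
        if abs(self.arm_angle * self.n_arms - 360.0) > 1e-9:
            raise ValueError("arm_angle * n_arms must equal 360")
        roles = {self.training_start_arm, self.target_arm, self.probe_start_arm}
        if roles != {0, 1, 2} and len(roles) != 3:
            raise ValueError("training_start_arm, target_arm, probe_start_arm must be distinct")
        if any(a not in range(self.n_arms)
               for a in (self.training_start_arm, self.target_arm, self.probe_start_arm)):
            raise ValueError("arm indices out of range")
        if self.criterion < 1:
            raise ValueError("criterion must be >= 1")


@dataclass(frozen=True)
class TownConfig:
    """Route-learning town: a fixed route over intersections plus pointing probes."""

    n_intersections: int = 16
    n_landmarks: int = 6
    pointing_repeats: int = 2
    route_turns: tuple[str, ...] = ()          # correct turn per intersection
    landmark_intersections: tuple[int, ...] = ()
    landmark_positions: tuple[tuple[float, float], ...] = ()
    block_size: float = 100.0                  # spacing of the intersection grid, m

    def __post_init__(self):
        if self.n_intersections < 1 or self.n_landmarks < 2:
            raise ValueError("need >= 1 intersection and >= 2 landmarks")
        if self.n_landmarks > self.n_intersections:
            raise ValueError("cannot place more landmarks than intersections")
        if not self.route_turns:
            rng = np.random.default_rng(11)
            object.__setattr__(
                self, "route_turns",
                tuple(str(t) for t in
                      rng.choice(["left", "straight", "right"], self.n_intersections)))
        if len(self.route_turns) != self.n_intersections:
            raise ValueError("route_turns must give one correct turn per intersection")
        if any(t not in ("left", "straight", "right") for t in self.route_turns):
            raise ValueError("turns must be left/straight/right")
        if not self.landmark_intersections:
            idx = np.linspace(0, self.n_intersections - 1, self.n_landmarks).round().astype(int)
            object.__setattr__(self, "landmark_intersections", tuple(int(i) for i in idx))
        if len(set(self.landmark_intersections)) != self.n_landmarks:
            raise ValueError("landmarks must sit at distinct route intersections")
        if any(i not in range(self.n_intersections) for i in self.landmark_intersections):
            raise ValueError("landmark intersections must lie on the route")
        if not self.landmark_positions:
            object.__setattr__(self, "landmark_positions",
                               tuple(self._route_layout()[i] for i in self.landmark_intersections))
        if len(self.landmark_positions) != self.n_landmarks:
            raise ValueError("one position per landmark required")

    def _route_layout(self) -> list[tuple[float, float]]:
        """2-D coordinates of route intersections, following the turn sequence."""
        pos = (0.0, 0.0)
        heading = 90.0
        out = [pos]
        turn_delta = {"left": 90.0, "straight": 0.0, "right": -90.0}
        for t in self.route_turns[:-1]:
            heading = (heading + turn_delta[t]) % 360.0
            rad = math.radians(heading)
            pos = (pos[0] + self.block_size * math.cos(rad),
                   pos[1] + self.block_size * math.sin(rad))
            out.append(pos)
        return out

    @property
    def n_pointing_trials(self) -> int:
        return math.comb(self.n_landmarks, 2) * self.pointing_repeats


def config_to_yaml(cfg, path) -> None:
    """Serialize any of the config dataclasses to YAML."""
    payload = {"type": type(cfg).__name__, "fields": dataclasses.asdict(cfg)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


_CONFIG_TYPES = {"ArenaConfig": ArenaConfig, "NavigatorParams": NavigatorParams,
                 "YMazeConfig": YMazeConfig, "TownConfig": TownConfig}


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


def config_from_yaml(path):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cls = _CONFIG_TYPES[payload["type"]]
    fields = {k: _tuplify(v) for k, v in payload["fields"].items()}
    return cls(**fields)
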