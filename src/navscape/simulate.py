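"""Seeded synthetic navigators for the three task environments.

The arena navigator is a waypoint-steering agent: it walks at fixed speed
toward its (noisy) memory of the cued object location, with optional
thigmotaxis implemented as an attraction toward the ring of radius
``bias * R``, Gaussian heading jitter, and random idle pauses.  The Y-maze
and town agents are discrete policy agents over the maze/route graphs.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .config import ArenaConfig, NavigatorParams, TownConfig, YMazeConfig
from .records import (PHASE_DROPOFF, PHASE_RETRIEVAL, DropEvent, PointingTrial,
                      Trajectory, TownRecord, YMazeRecord)

__all__ = ["simulate_arena_session", "simulate_ymaze", "simulate_town",
           "turn_between_arms", "apply_turn"]

# fraction of the arena radius the agent treats as an impassable bank
_WALL_MARGIN = 0.995
# distance (U.u.) at which the agent considers a waypoint reached
ARRIVAL_TOL = 120.0
# give-up time per navigation leg, s; on timeout the object is dropped in place
MAX_LEG_DURATION = 150.0
# stationary dwell while feedback is displayed, s
FEEDBACK_DWELL = 1.5


def _clip_step(pos: np.ndarray, step: np.ndarray, r_max: float) -> np.ndarray:
    """Advance pos by step, stopping at the arena bank (never exceeding |step|)."""
    new = pos + step
    if new[0] * new[0] + new[1] * new[1] <= r_max * r_max:
        return new
    # solve |pos + a*step| = r_max for the largest a in [0, 1]
    a_coef = step @ step
    b_coef = 2.0 * (pos @ step)
    c_coef = pos @ pos - r_max * r_max
    disc = max(b_coef * b_coef - 4 * a_coef * c_coef, 0.0)
    alpha = (-b_coef + math.sqrt(disc)) / (2 * a_coef) if a_coef > 0 else 0.0
    return pos + max(min(alpha, 1.0), 0.0) * step


def _steer(pos: np.ndarray, goal: np.ndarray, bias: float, radius: float) -> np.ndarray:
    """Unit steering direction blending goal pursuit with ring attraction."""
    d = goal - pos
    dist = math.hypot(d[0], d[1])
    u_goal = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
    # thigmotaxis relaxes close to the goal: the agent hugs the ring while
    # traveling but darts in for the final approach
    bias = bias * min(1.0, dist / (0.3 * radius))
    if bias <= 0.0:
        return u_goal
    r = math.hypot(pos[0], pos[1])
    u_out = pos / r if r > 1e-9 else np.array([1.0, 0.0])
    r_star = bias * radius
    # center avoidance: push outward toward the ring, never inward off it
    radial = u_out * max(min(12.0 * (r_star - r) / radius, 1.0), 0.0)
    # tangential wall-following travel, active only while the ring constraint
    # is engaged (at or below the ring), in the direction closing the angle
    # to the goal
    engagement = max(min(4.0 * (r_star + 0.1 * radius - r) / radius, 1.0), 0.0)
    ang_gap = math.atan2(goal[1], goal[0]) - math.atan2(pos[1], pos[0])
    ang_gap = (ang_gap + math.pi) % (2 * math.pi) - math.pi
    tang_sign = 1.0 if ang_gap >= 0 else -1.0
    u_tan = np.array([-u_out[1], u_out[0]]) * (tang_sign * engagement)
    u_thig = radial + u_tan
    nrm = math.hypot(u_thig[0], u_thig[1])
    if nrm < 1e-9:
        return u_goal
    blended = (1.0 - bias) * u_goal + bias * (u_thig / nrm)
    nrm = math.hypot(blended[0], blended[1])
    return blended / nrm if nrm > 1e-9 else u_goal


class _Walker:
    """Incremental sample recorder for one arena session."""

    def __init__(self, cfg: ArenaConfig, nav: NavigatorParams, rng: np.random.Generator,
                 pos: np.ndarray):
        self.cfg, self.nav, self.rng = cfg, nav, rng
        self.dt = 1.0 / cfg.sample_rate
        self.pos = pos.copy()
        self.t = 0.0
        self.pause_left = 0.0
        self.ts: list[float] = []
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.phases: list[str] = []
        self.jitter_rad = math.radians(nav.heading_jitter_sd)

    def _record(self, phase: str) -> None:
        self.ts.append(self.t)
        self.xs.append(float(self.pos[0]))
        self.ys.append(float(self.pos[1]))
        self.phases.append(phase)

    def dwell(self, duration: float, phase: str) -> None:
        end = self.t + duration
        while self.t < end - 1e-9:
            self.t += self.dt
            self._record(phase)

    def walk_to(self, goal: np.ndarray, phase: str, max_duration: float = MAX_LEG_DURATION
                ) -> bool:
        """Walk toward goal; True if reached within max_duration."""
        nav, cfg = self.nav, self.cfg
        r_max = cfg.radius * _WALL_MARGIN
        elapsed = 0.0
        while elapsed < max_duration:
            self.t += self.dt
            elapsed += self.dt
            if self.pause_left > 0.0:
                self.pause_left -= self.dt
            elif nav.idle_prob > 0.0 and self.rng.random() < nav.idle_prob:
                self.pause_left = self.rng.exponential(nav.idle_dwell)
            else:
                u = _steer(self.pos, goal, nav.thigmotaxis_bias, cfg.radius)
                if self.jitter_rad > 0.0:
                    th = math.atan2(u[1], u[0]) + self.rng.normal(0.0, self.jitter_rad)
                    u = np.array([math.cos(th), math.sin(th)])
                self.pos = _clip_step(self.pos, u * (nav.speed * self.dt), r_max)
            self._record(phase)
            d = goal - self.pos
            if math.hypot(d[0], d[1]) <= ARRIVAL_TOL:
                return True
        return False


def simulate_arena_session(cfg: ArenaConfig, nav: NavigatorParams
                           ) -> tuple[Trajectory, list[DropEvent]]:
    """Simulate one object drop-off session in the circular arena.

    Objects are cued in randomized complete cycles of all ``n_targets``
    locations, so per-object repetition counts never differ by more than one.
    A drop-off in progress when the session clock runs out is completed.
    Each trial contributes a cue→drop navigation leg (phase ``dropoff_nav``)
    followed by a feedback dwell and a walk back to the true location to
    re-collect the object (phase ``retrieval``).
    """
    rng = np.random.default_rng(nav.seed)
    targets = np.asarray(cfg.target_positions, dtype=float)
    r_max = cfg.radius * _WALL_MARGIN

    def recall(obj: int) -> np.ndarray:
        """Remembered location: true position plus fresh isotropic memory error."""
        if nav.memory_noise_sd <= 0:
            return targets[obj].copy()
        rem = targets[obj] + rng.normal(0.0, nav.memory_noise_sd, size=2)
        rad = math.hypot(rem[0], rem[1])
        if rad > r_max:  # memory cannot place an object beyond the banks
            rem *= r_max / rad
        return rem

    ang = rng.uniform(0.0, 2 * math.pi)
    start = np.array([cfg.start_radius * math.cos(ang), cfg.start_radius * math.sin(ang)])
    walker = _Walker(cfg, nav, rng, start)
    walker._record(PHASE_DROPOFF)

    events: list[DropEvent] = []
    reps = np.zeros(cfg.n_targets, dtype=int)
    session_end = cfg.session_duration
    cycle: list[int] = []
    while walker.t < session_end:
        if not cycle:
            cycle = list(rng.permutation(cfg.n_targets))
        obj = int(cycle.pop())
        remembered = recall(obj)
        cue_time = walker.t
        reached = walker.walk_to(remembered, PHASE_DROPOFF)
        drop_pos = remembered if reached else walker.pos.copy()
        reps[obj] += 1
        events.append(DropEvent(obj, int(reps[obj]), cue_time, walker.t,
                                (float(drop_pos[0]), float(drop_pos[1])),
                                (float(targets[obj, 0]), float(targets[obj, 1]))))
        walker.dwell(FEEDBACK_DWELL, PHASE_RETRIEVAL)
        walker.walk_to(targets[obj], PHASE_RETRIEVAL)

    traj = Trajectory(np.array(walker.ts), np.array(walker.xs), np.array(walker.ys),
                      np.array(walker.phases), seed=nav.seed)
    return traj, events


# ------------------------------------------------------------------ Y-maze

def turn_between_arms(from_arm: int, to_arm: int, n_arms: int = 3) -> str:
    """Body turn (left/right) taking the agent from one arm's end to another.

    Convention: from arm ``a``, a left turn at the hub leads into arm
    ``(a+1) % 3``, a right turn into ``(a+2) % 3``.
    """
    delta = (to_arm - from_arm) % n_arms
    if delta == 1:
        return "left"
    if delta == 2:
        return "right"
    raise ValueError("cannot turn back into the same arm")


def apply_turn(from_arm: int, turn: str, n_arms: int = 3) -> int:
    if turn == "left":
        return (from_arm + 1) % n_arms
    if turn == "right":
        return (from_arm + 2) % n_arms
    raise ValueError(f"unknown turn {turn!r}")


def _ymaze_error_prob(nav: NavigatorParams) -> float:
    """Map spatial-memory noise onto a per-trial wrong-turn probability."""
    return min(nav.memory_noise_sd / 5000.0, 0.49)


def simulate_ymaze(cfg: YMazeConfig, nav: NavigatorParams, max_trials: int = 500
                   ) -> YMazeRecord:
    """Train to criterion from a fixed arm, then probe from the third arm.

    Allocentric agents head for the cue-defined target arm wherever they
    start; egocentric agents repeat the trained body turn.  ``mixed``
    agents pick one of the two policies at random for the probe.
    """
    if nav.strategy not in ("allocentric", "egocentric", "mixed"):
        raise ValueError(f"unsupported strategy {nav.strategy!r}")
    rng = np.random.default_rng(nav.seed)
    correct_turn = turn_between_arms(cfg.training_start_arm, cfg.target_arm)
    wrong_turn = "right" if correct_turn == "left" else "left"
    p_err = _ymaze_error_prob(nav)

    turns: list[str] = []
    correct: list[bool] = []
    streak = 0
    while streak < cfg.criterion:
        if len(turns) >= max_trials:
            raise RuntimeError(
                f"training criterion unreachable within {max_trials} trials "
                f"(error probability {p_err})")
        turn = wrong_turn if rng.random() < p_err else correct_turn
        ok = turn == correct_turn
        streak = streak + 1 if ok else 0
        turns.append(turn)
        correct.append(ok)

    strategy = nav.strategy
    if strategy == "mixed":
        strategy = "allocentric" if rng.random() < 0.5 else "egocentric"
    if strategy == "allocentric":
        probe_turn = turn_between_arms(cfg.probe_start_arm, cfg.target_arm)
        if rng.random() < p_err:
            probe_turn = "right" if probe_turn == "left" else "left"
        noticed = False
    else:
        probe_turn = correct_turn  # the learned motor response, replayed
        noticed = rng.random() < nav.notice_change_prob
    reached = apply_turn(cfg.probe_start_arm, probe_turn)
    return YMazeRecord(tuple(turns), tuple(correct), correct_turn,
                       cfg.probe_start_arm, probe_turn, reached, noticed,
                       cfg.target_arm, cfg.training_start_arm)


# -------------------------------------------------------------------- town

def simulate_town(cfg: TownConfig, turn_error_prob: float, pointing_noise_sd: float,
                  seed: int, rt_median: float = 3.0, rt_log_sd: float = 0.4,
                  max_rounds: int = 200) -> TownRecord:
    """Simulate route learning (probe runs until error-free) plus pointing.

    Every probe run stops at all intersections; a wrong turn occurs
    independently with ``turn_error_prob`` at each stop.  Pointing tests all
    unordered landmark pairs ``pointing_repeats`` times (both directions when
    repeats = 2) with wrapped-Gaussian angular noise and log-normal RTs.
    """
    if not 0.0 <= turn_error_prob <= 1.0:
        raise ValueError("turn_error_prob must be in [0, 1]")
    if pointing_noise_sd < 0:
        raise ValueError("pointing_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    probes: list[tuple[bool, ...]] = []
    while True:
        errs = rng.random(cfg.n_intersections) < turn_error_prob
        probes.append(tuple(bool(e) for e in errs))
        if not errs.any():
            break
        if len(probes) >= max_rounds:
            raise RuntimeError(f"route never learned within {max_rounds} probe runs")

    pos = np.asarray(cfg.landmark_positions, dtype=float)
    pairs = list(combinations(range(cfg.n_landmarks), 2))
    trials: list[PointingTrial] = []
    for rep in range(cfg.pointing_repeats):
        for i, j in pairs:
            a, b = (i, j) if rep % 2 == 0 else (j, i)  # alternate direction
            d = pos[b] - pos[a]
            true_bearing = math.degrees(math.atan2(d[1], d[0])) % 360.0
            resp = (true_bearing + rng.normal(0.0, pointing_noise_sd)) % 360.0 \
                if pointing_noise_sd > 0 else true_bearing
            rt = float(rng.lognormal(math.log(rt_median), rt_log_sd))
            trials.append(PointingTrial(a, b, true_bearing, resp, rt))
    order = rng.permutation(len(trials))
    trials = [trials[k] for k in order]
    return TownRecord(tuple(probes), tuple(trials), cfg.n_intersections)
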