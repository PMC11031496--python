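"""Per-trial and per-path movement and memory metrics.

Covers the arena outcome measures: drop error, periphery (thigmotaxis)
preference, per-path movement metrics (distance, sinuosity, maximum
deviation from the straight path, x-/y-flips, idle time), and the two
integrated speed–accuracy scores, AUC and LISAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .records import DropEvent, Trajectory

__all__ = [
    "drop_error", "periphery_preference", "path_metrics", "lisas",
    "auc_speed_accuracy", "idle_time", "speed_accuracy", "PathMetrics",
    "SpeedAccuracy", "enumerate_path_ids", "trial_paths", "START_LOCATION",
]

START_LOCATION = "start"


def drop_error(drop: Sequence[float], target: Sequence[float]) -> float:
    """Euclidean distance (U.u.) between drop-off point and true location."""
    dx, dy = drop[0] - target[0], drop[1] - target[1]
    if not (math.isfinite(dx) and math.isfinite(dy)):
        raise ValueError("non-finite coordinates")
    return math.hypot(dx, dy)


def periphery_preference(traj: Trajectory, radius: float, *,
                         boundary: str = "half", phase: str | None = None) -> float:
    """Proportion of movement samples in the outer part of the arena.

    ``boundary='half'`` places the periphery cut at the radial midpoint
    ``R/2``; ``'equal_area'`` uses ``R/sqrt(2)``, which splits the disc into
    equal areas.  Optionally restrict to one phase (e.g. object retrieval).
    """
    if phase is not None:
        traj = traj.filter_phase(phase)
    if len(traj) == 0:
        raise ValueError("no samples after phase filtering")
    if boundary == "half":
        cut = radius / 2.0
    elif boundary == "equal_area":
        cut = radius / math.sqrt(2.0)
    else:
        raise ValueError(f"unknown boundary rule {boundary!r}")
    return float(np.mean(traj.r > cut))


@dataclass(frozen=True)
class PathMetrics:
    """Movement metrics of one path between two known arena locations."""

    path_id: tuple
    distance_traveled: float
    crow_distance: float
    sinuosity: float            # nan when crow_distance == 0 (see sinuosity_defined)
    max_abs_deviation: float
    x_flips: int
    y_flips: int
    idle_time: float
    duration: float

    @property
    def sinuosity_defined(self) -> bool:
        return math.isfinite(self.sinuosity)


def _debounced_flips(steps: np.ndarray, min_disp: float) -> int:
    """Count direction changes of one velocity component.

    Consecutive same-sign displacements are merged into legs; legs whose
    total displacement is below ``min_disp`` are treated as sampling jitter
    and dropped (adjacent same-sign legs then merge) before counting sign
    changes.
    """
    signs = np.sign(steps)
    legs: list[float] = []
    for s, d in zip(signs, steps):
        if s == 0:
            continue
        if legs and math.copysign(1.0, legs[-1]) == s:
            legs[-1] += d
        else:
            legs.append(d)
    kept: list[float] = []
    for d in legs:
        if abs(d) < min_disp:
            continue
        if kept and math.copysign(1.0, kept[-1]) == math.copysign(1.0, d):
            kept[-1] += d
        else:
            kept.append(d)
    return max(len(kept) - 1, 0)


def idle_time(traj: Trajectory, idle_speed_eps: float) -> float:
    """Total time (s) spent in sample intervals slower than ``idle_speed_eps``."""
    if len(traj) < 2:
        return 0.0
    dt = np.diff(traj.t)
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(dt[disp / dt < idle_speed_eps].sum())


def path_metrics(traj: Trajectory, endpoints: tuple, *,
                 idle_speed_eps: float, flip_min_disp: float = 50.0,
                 path_id: tuple = ()) -> PathMetrics:
    """Movement metrics of one trajectory segment between two locations.

    ``endpoints`` are the nominal (from, to) locations defining the straight
    reference path.  When the endpoints coincide (zero crow distance),
    sinuosity is undefined and reported as nan rather than coerced.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples")
    p0 = np.asarray(endpoints[0], dtype=float)
    p1 = np.asarray(endpoints[1], dtype=float)
    steps_x = np.diff(traj.x)
    steps_y = np.diff(traj.y)
    distance = float(np.hypot(steps_x, steps_y).sum())
    crow = float(np.hypot(*(p1 - p0)))
    sinu = distance / crow if crow > 0 else float("nan")

    chord = p1 - p0
    rel = traj.xy - p0
    if crow > 0:
        dev = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / crow
    else:
        dev = np.hypot(rel[:, 0], rel[:, 1])
    return PathMetrics(
        path_id=tuple(path_id),
        distance_traveled=distance,
        crow_distance=crow,
        sinuosity=sinu,
        max_abs_deviation=float(dev.max()),
        x_flips=_debounced_flips(steps_x, flip_min_disp),
        y_flips=_debounced_flips(steps_y, flip_min_disp),
        idle_time=idle_time(traj, idle_speed_eps),
        duration=float(traj.t[-1] - traj.t[0]),
    )


# ------------------------------------------------------- speed–accuracy

@dataclass(frozen=True)
class SpeedAccuracy:
    """Integrated speed–accuracy summaries for one participant."""

    auc: float                 # U.u.·s; higher = worse
    lisas: np.ndarray          # per-trial, same units as RT (s)
    sd_rt: float
    sd_de: float


def lisas(events: Sequence[DropEvent]) -> np.ndarray:
    """Linear integrated speed–accuracy score per trial.

    ``RT_i + (SD_RT / SD_DE) * DE_i`` with the standard deviations taken over
    all of the participant's trials, so the accuracy penalty is expressed in
    RT units.
    """
    if len(events) < 2:
        raise ValueError("LISAS needs >= 2 trials for the SD weights")
    rt = np.array([e.navigation_duration for e in events])
    de = np.array([e.drop_error for e in events])
    sd_rt = float(np.std(rt, ddof=1))
    sd_de = float(np.std(de, ddof=1))
    if sd_de == 0.0:
        if np.all(de == 0.0):
            return rt.copy()   # error-free performance: zero penalty
        raise ValueError("degenerate accuracy variance: all drop errors identical")
    return rt + (sd_rt / sd_de) * de


def auc_speed_accuracy(events: Sequence[DropEvent]) -> float:
    """Area under the drop-error curve over cumulative navigation duration.

    Trapezoidal area of DE against cumulative RT, with the curve extended
    left-constant to time zero; higher area means slower and/or less
    accurate performance.
    """
    if len(events) < 2:
        raise ValueError("AUC undefined for fewer than 2 trials")
    rt = np.array([e.navigation_duration for e in events])
    de = np.array([e.drop_error for e in events])
    x = np.concatenate([[0.0], np.cumsum(rt)])
    y = np.concatenate([[de[0]], de])
    return float(np.trapezoid(y, x))


def speed_accuracy(events: Sequence[DropEvent]) -> SpeedAccuracy:
    rt = np.array([e.navigation_duration for e in events])
    de = np.array([e.drop_error for e in events])
    return SpeedAccuracy(auc=auc_speed_accuracy(events), lisas=lisas(events),
                         sd_rt=float(np.std(rt, ddof=1)), sd_de=float(np.std(de, ddof=1)))


# ----------------------------------------------------------- path layer

def enumerate_path_ids(n_targets: int = 8) -> list[tuple]:
    """All unordered pairs of the start point and the target locations.

    With 8 targets this is the C(9,2) = 36 possible paths between known
    locations, direction ignored.
    """
    points = [START_LOCATION] + list(range(n_targets))
    return [tuple(sorted(p, key=str)) for p in combinations(points, 2)]


def trial_paths(traj: Trajectory, events: Sequence[DropEvent], *,
                idle_speed_eps: float, flip_min_disp: float = 50.0
                ) -> pd.DataFrame:
    """Per-trial path metrics over the cue→drop navigation legs.

    Each drop-off leg runs from the previous trial's (true) location — or the
    session start point for the first trial — to the current remembered
    location; the nominal endpoints are the known locations, giving the
    unordered location-pair ``path_id``.  The straight-path reference uses
    the actual segment endpoints (where the agent really started and
    dropped), so sinuosity is a genuine traveled/straight ratio >= 1.
    """
    rows = []
    prev_loc: object = START_LOCATION
    for ev in events:
        seg = traj.slice_time(ev.cue_time, ev.drop_time)
        if len(seg) < 2:
            prev_loc = ev.object_id
            continue
        pid = tuple(sorted((prev_loc, ev.object_id), key=str))
        pm = path_metrics(seg, (seg.xy[0], seg.xy[-1]),
                          idle_speed_eps=idle_speed_eps,
                          flip_min_disp=flip_min_disp, path_id=pid)
        rows.append({
            "path_id": str(pid), "object_id": ev.object_id,
            "repetition_index": ev.repetition_index,
            "navigation_duration": ev.navigation_duration,
            "drop_error": ev.drop_error,
            "distance_traveled": pm.distance_traveled,
            "crow_distance": pm.crow_distance,
            "sinuosity": pm.sinuosity,
            "max_abs_deviation": pm.max_abs_deviation,
            "x_flips": pm.x_flips, "y_flips": pm.y_flips,
            "idle_time": pm.idle_time,
        })
        prev_loc = ev.object_id
    return pd.DataFrame(rows)
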