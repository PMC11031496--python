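"""In-memory records produced by the simulators and consumed by the analyses.

Trajectories are thin wrappers over numpy arrays with tidy-CSV round trips
(participant, session, t, x, y, phase); event and task records are plain
dataclasses.  All CSV writers put the generating seed in a ``# seed=`` header
comment so any file can be traced back to its generator call.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory", "DropEvent", "YMazeRecord", "TownRecord", "PointingTrial",
    "write_trajectory_csv", "read_trajectory_csv",
    "write_events_csv", "read_events_csv",
]

# phase labels for arena samples
PHASE_DROPOFF = "dropoff_nav"
PHASE_RETRIEVAL = "retrieval"
PHASE_ENCODING = "encoding"


@dataclass
class Trajectory:
    """Ordered time-stamped 2-D positions for one participant/session."""

    t: np.ndarray                     # s, strictly increasing
    x: np.ndarray                     # U.u.
    y: np.ndarray                     # U.u.
    phase: np.ndarray                 # per-sample str label
    participant: str = "p0"
    session: str = "s0"
    sex: str | None = None            # 'F' | 'M'
    treatment: str | None = None      # 'PBO' | 'E2V'
    seed: int | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phase = np.asarray(self.phase)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.phase) == n):
            raise ValueError("t, x, y, phase must have equal length")
        if n and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def r(self) -> np.ndarray:
        """Radial distance of each sample from the arena center."""
        return np.hypot(self.x, self.y)

    def filter_phase(self, phase: str) -> "Trajectory":
        m = self.phase == phase
        return Trajectory(self.t[m], self.x[m], self.y[m], self.phase[m],
                          self.participant, self.session, self.sex, self.treatment, self.seed)

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        m = (self.t >= t0) & (self.t <= t1)
        return Trajectory(self.t[m], self.x[m], self.y[m], self.phase[m],
                          self.participant, self.session, self.sex, self.treatment, self.seed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant, "session": self.session,
            "sex": self.sex, "treatment": self.treatment,
            "t": self.t, "x": self.x, "y": self.y, "phase": self.phase,
        })


@dataclass(frozen=True)
class DropEvent:
    """One object drop-off trial in the arena."""

    object_id: int
    repetition_index: int            # per-object count; proxy for time-on-task
    cue_time: float                  # s
    drop_time: float                 # s
    drop_position: tuple[float, float]
    target_position: tuple[float, float]

    @property
    def navigation_duration(self) -> float:
        """RT of the trial: cue onset to drop, s."""
        return self.drop_time - self.cue_time

    @property
    def drop_error(self) -> float:
        """Euclidean distance (U.u.) from drop to true target location."""
        dx = self.drop_position[0] - self.target_position[0]
        dy = self.drop_position[1] - self.target_position[1]
        return float(np.hypot(dx, dy))

    def __post_init__(self):
        if not self.drop_time > self.cue_time:
            raise ValueError("navigation duration must be positive")


@dataclass(frozen=True)
class YMazeRecord:
    """Training outcomes plus the probe trial of one Y-maze session."""

    training_turns: tuple[str, ...]       # turn taken on each training trial
    training_correct: tuple[bool, ...]
    training_turn: str                    # turn of the learned (criterion) sequence
    probe_start_arm: int
    probe_turn: str
    probe_arm_reached: int
    noticed_change: bool
    target_arm: int
    training_start_arm: int


@dataclass(frozen=True)
class PointingTrial:
    """One landmark-to-landmark pointing probe."""

    from_landmark: int
    to_landmark: int
    true_bearing: float       # deg
    response_bearing: float   # deg
    rt: float                 # s, > 0


@dataclass(frozen=True)
class TownRecord:
    """Route-learning rounds and pointing trials of one town session.

    ``probe_errors`` holds one boolean vector per probe run (True = wrong
    turn at that intersection); the learning-cycle loop ran until the last
    vector is all-False.
    """

    probe_errors: tuple[tuple[bool, ...], ...]
    pointing_trials: tuple[PointingTrial, ...]
    n_intersections: int


# ---------------------------------------------------------------- CSV I/O

def _write_with_seed(df: pd.DataFrame, path, seed) -> None:
    buf = io.StringIO()
    buf.write(f"# seed={seed}\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_trajectory_csv(trajs, path, seed=None) -> None:
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    if seed is None:
        seed = trajs[0].seed
    _write_with_seed(pd.concat([t.to_frame() for t in trajs], ignore_index=True), path, seed)


def read_trajectory_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for (p, s), g in df.groupby(["participant", "session"], sort=False):
        sex = g["sex"].iloc[0] if "sex" in g else None
        trt = g["treatment"].iloc[0] if "treatment" in g else None
        out.append(Trajectory(g["t"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy(),
                              g["phase"].to_numpy(), str(p), str(s),
                              None if pd.isna(sex) else sex,
                              None if pd.isna(trt) else trt))
    return out


def events_to_frame(events, participant="p0") -> pd.DataFrame:
    return pd.DataFrame([{
        "participant": participant,
        "object_id": e.object_id, "repetition_index": e.repetition_index,
        "cue_time": e.cue_time, "drop_time": e.drop_time,
        "navigation_duration": e.navigation_duration,
        "drop_x": e.drop_position[0], "drop_y": e.drop_position[1],
        "target_x": e.target_position[0], "target_y": e.target_position[1],
        "drop_error": e.drop_error,
    } for e in events])


def write_events_csv(events, path, seed=None, participant="p0") -> None:
    _write_with_seed(events_to_frame(events, participant), path, seed)


def read_events_csv(path) -> list[DropEvent]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [DropEvent(int(r.object_id), int(r.repetition_index), float(r.cue_time),
                      float(r.drop_time), (float(r.drop_x), float(r.drop_y)),
                      (float(r.target_x), float(r.target_y)))
            for r in df.itertuples()]
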