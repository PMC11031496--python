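"""Rule-based scoring of the three tasks.

Y-maze probe trials are classified as allocentric (reached the cue-defined
target arm via a different body turn), egocentric (repeated the trained
turn), or ego+ (egocentric movement but the participant reported noticing
the cue change — excluded from strategy analyses).  Town records yield
rounds-to-criterion and cumulative route errors plus pointing-error
scoring; arena drop errors map onto the five-grade feedback scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import TownRecord, YMazeRecord

__all__ = ["YMazeOutcome", "TownRouteResult", "classify_ymaze",
           "score_town_route", "pointing_error", "score_pointing",
           "feedback_grade", "DEFAULT_FEEDBACK_THRESHOLDS"]

# five feedback grades: best within 700 U.u., worst beyond 4500 U.u.;
# interior cuts are an equally spaced convention (not part of the task spec)
DEFAULT_FEEDBACK_THRESHOLDS = (700.0, 700 + 3800 / 3, 700 + 2 * 3800 / 3, 4500.0)

LABEL_ALLO = "allocentric"
LABEL_EGO = "egocentric"
LABEL_EGO_PLUS = "ego_plus_excluded"


@dataclass(frozen=True)
class YMazeOutcome:
    label: str
    probe_arm_reached: int
    noticed_change: bool


@dataclass(frozen=True)
class TownRouteResult:
    rounds_to_criterion: int          # >= 2 by task design
    cumulative_errors: int
    per_round_errors: tuple[tuple[bool, ...], ...]


def classify_ymaze(record: YMazeRecord) -> YMazeOutcome:
    """Strategy label from the probe trial of a Y-maze record.

    Repeating the trained turn sequence from the new start arm is egocentric
    navigation (it cannot lead to the target arm); reaching the cue-defined
    target arm via a different turn is allocentric.  Egocentric movers who
    reported noticing the cue change are labelled for exclusion.
    """
    if record.probe_arm_reached == record.probe_start_arm:
        raise ValueError("malformed record: probe cannot end in its own start arm")
    if record.probe_turn == record.training_turn:
        label = LABEL_EGO_PLUS if record.noticed_change else LABEL_EGO
    elif record.probe_arm_reached == record.target_arm:
        label = LABEL_ALLO
    else:
        raise ValueError("malformed record: non-trained turn must reach the target arm")
    return YMazeOutcome(label, record.probe_arm_reached, record.noticed_change)


def score_town_route(record: TownRecord) -> TownRouteResult:
    """Rounds-to-criterion and cumulative turning errors of a town record.

    The two initial passive learning runs count as the first two rounds, so
    an error-free navigator scores the task minimum of 2; every failed probe
    adds one learning cycle (one more round).  Errors are summed across all
    probe runs, not only the last.
    """
    if not record.probe_errors:
        raise ValueError("record has no probe runs")
    if any(len(run) != record.n_intersections for run in record.probe_errors):
        raise ValueError("each probe run must stop at every intersection")
    if any(record.probe_errors[-1]):
        raise ValueError("record terminated without reaching the error-free criterion")
    rounds = 1 + len(record.probe_errors)
    errors = int(sum(sum(run) for run in record.probe_errors))
    return TownRouteResult(rounds, errors, record.probe_errors)


def pointing_error(true_bearing: float, response_bearing: float) -> float:
    """Minimal absolute angular difference between two bearings, in [0, 180]."""
    if not (math.isfinite(true_bearing) and math.isfinite(response_bearing)):
        raise ValueError("bearings must be finite")
    d = abs(true_bearing - response_bearing) % 360.0
    return min(d, 360.0 - d)


def score_pointing(record: TownRecord) -> pd.DataFrame:
    """Tidy per-trial pointing errors and response times."""
    return pd.DataFrame([{
        "from_landmark": t.from_landmark, "to_landmark": t.to_landmark,
        "true_bearing": t.true_bearing, "response_bearing": t.response_bearing,
        "pointing_error": pointing_error(t.true_bearing, t.response_bearing),
        "rt": t.rt,
    } for t in record.pointing_trials])


def feedback_grade(de: float, thresholds=DEFAULT_FEEDBACK_THRESHOLDS) -> int:
    """Five-grade drop-off feedback: 1 (within 700 U.u.) … 5 (beyond 4500).

    Cut points are lower-grade inclusive: a drop error exactly on a cut
    receives the better grade.
    """
    if de < 0 or not math.isfinite(de):
        raise ValueError("drop error must be a finite non-negative length")
    cuts = tuple(thresholds)
    if len(cuts) != 4 or any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("thresholds must be 4 strictly increasing cut points")
    return 1 + int(sum(de > c for c in cuts))
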