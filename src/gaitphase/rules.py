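"""Threshold rule-based transition and gait-phase detection state machine.

The detector evaluates, once per 100 Hz sample, a fixed bank of
conjunctive threshold conditions (one row per detectable state) on the
insole GRF/COP signals, the summed joint flexion, the windowed GRF
asymmetry (grfDiff) and the foot angular velocities.  Each row that is
fully satisfied proposes its flag; the next state is chosen from the
proposals by the rules below, and if nothing fires the previous flag is
retained.

Two published transcription slips in the source rule table are corrected
here (both are obvious from the surrounding rows and the prose):

* the initiation / termination rows compare *both* feet against QSgrf
  (the prose repeats grfL twice);
* the right-left double-stance row requires ``sumAng > minAng`` (some
  flexion remaining), mirroring the left-right row; the printed
  ``sumAng < midAng`` references a threshold that does not exist.

Proposal arbitration.  The quiet-standing rows and the termination row
are *transitions with designated source states* (quiet standing is
reached from initiation or termination; termination from a double
stance), so they are only considered when the detector is in a matching
state.  The walking-phase rows and the initiation row are evaluated from
any state ("free" mode): the detector is deliberately not restricted to
the gait-cycle series, so a missed phase is skipped and detection
resumes at the next phase.  When several applicable rows fire at once,
double-stance rows win over single-stance rows (their foot-contact
conditions are strictly stronger and would otherwise be shadowed), which
win over initiation/termination, which win over quiet standing.

In "strict" mode the detector additionally accepts only transitions that
exist in the state diagram (the behaviour of a downstream finite-state
prosthesis controller): a proposal that is not reachable from the
current state leaves the state unchanged.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    GRF_DIFF_WINDOW,
    DerivedSignals,
    LabeledTrial,
    PhaseFlag,
    SensorFrame,
    ThresholdSet,
    grf_diff,
    grf_diff_series,
    sum_ang,
)

# Row identifiers, named after the state each row detects.
ROW_QS_FROM_INIT = "quiet_from_initiation"
ROW_QS_FROM_TERM = "quiet_from_termination"
ROW_INITIATION = "initiation"
ROW_TERMINATION = "termination"
ROW_LEFT_STANCE = "left_stance"
ROW_LR_DOUBLE = "lr_double_stance"
ROW_RIGHT_STANCE = "right_stance"
ROW_RL_DOUBLE = "rl_double_stance"

ROW_FLAG: dict[str, PhaseFlag] = {
    ROW_QS_FROM_INIT: PhaseFlag.QUIET_STANDING,
    ROW_QS_FROM_TERM: PhaseFlag.QUIET_STANDING,
    ROW_INITIATION: PhaseFlag.INITIATION,
    ROW_TERMINATION: PhaseFlag.TERMINATION,
    ROW_LEFT_STANCE: PhaseFlag.LEFT_STANCE,
    ROW_LR_DOUBLE: PhaseFlag.LR_DOUBLE,
    ROW_RIGHT_STANCE: PhaseFlag.RIGHT_STANCE,
    ROW_RL_DOUBLE: PhaseFlag.RL_DOUBLE,
}

#: Arbitration order among applicable fired rows.
ROW_PRIORITY = (
    ROW_LR_DOUBLE,
    ROW_RL_DOUBLE,
    ROW_LEFT_STANCE,
    ROW_RIGHT_STANCE,
    ROW_INITIATION,
    ROW_TERMINATION,
    ROW_QS_FROM_INIT,
    ROW_QS_FROM_TERM,
)

_ANY_STATE = frozenset(PhaseFlag)
_WALKING = frozenset(
    {PhaseFlag.LEFT_STANCE, PhaseFlag.LR_DOUBLE, PhaseFlag.RIGHT_STANCE, PhaseFlag.RL_DOUBLE}
)

#: Source states from which each row may be taken (free mode).  Rows for
#: walking phases and initiation are state-free; quiet standing and
#: termination are transitions bound to their source states (UNKNOWN is
#: added to the quiet-standing rows so a trial that starts standing is
#: classified immediately; termination is not its own source, otherwise
#: it would keep re-firing during stable standing and shadow the
#: return to quiet standing).
ROW_SOURCES: dict[str, frozenset[PhaseFlag]] = {
    ROW_LEFT_STANCE: _ANY_STATE,
    ROW_LR_DOUBLE: _ANY_STATE,
    ROW_RIGHT_STANCE: _ANY_STATE,
    ROW_RL_DOUBLE: _ANY_STATE,
    ROW_INITIATION: _ANY_STATE,
    ROW_TERMINATION: _WALKING,
    ROW_QS_FROM_INIT: frozenset(
        {PhaseFlag.INITIATION, PhaseFlag.QUIET_STANDING, PhaseFlag.UNKNOWN}
    ),
    ROW_QS_FROM_TERM: frozenset(
        {PhaseFlag.TERMINATION, PhaseFlag.QUIET_STANDING, PhaseFlag.UNKNOWN}
    ),
}

#: State-diagram topology: allowed transitions for strict mode
#: (a: 5->6, b: 6->5, c: 6->11/13, d: 14->11, e: 11->12, f: 12->13,
#:  g: 13->14, h/i: 12->4 and 14->4, j: 4->5).
TOPOLOGY: dict[PhaseFlag, frozenset[PhaseFlag]] = {
    PhaseFlag.QUIET_STANDING: frozenset({PhaseFlag.INITIATION}),
    PhaseFlag.INITIATION: frozenset(
        {PhaseFlag.QUIET_STANDING, PhaseFlag.LEFT_STANCE, PhaseFlag.RIGHT_STANCE}
    ),
    PhaseFlag.LEFT_STANCE: frozenset({PhaseFlag.LR_DOUBLE}),
    PhaseFlag.LR_DOUBLE: frozenset({PhaseFlag.RIGHT_STANCE, PhaseFlag.TERMINATION}),
    PhaseFlag.RIGHT_STANCE: frozenset({PhaseFlag.RL_DOUBLE}),
    PhaseFlag.RL_DOUBLE: frozenset({PhaseFlag.LEFT_STANCE, PhaseFlag.TERMINATION}),
    PhaseFlag.TERMINATION: frozenset({PhaseFlag.QUIET_STANDING}),
    # Before the first classification any state may be entered.
    PhaseFlag.UNKNOWN: frozenset(PhaseFlag) - {PhaseFlag.UNKNOWN},
}


def eval_row_conditions(
    frame: SensorFrame, derived: DerivedSignals, th: ThresholdSet
) -> dict[str, bool]:
    """Evaluate every condition row on one frame.

    A NaN (sentinel) COP makes any COP comparison False, so an unloaded
    foot can never satisfy a double-stance COP condition.
    """
    grfL, grfR = frame.grfL, frame.grfR
    copyL, copyR = frame.copyL, frame.copyR
    gyroL, gyroR = frame.gyroL, frame.gyroR
    gd, sa = derived.grfDiff, derived.sumAng

    quiet = gd < th.init2 and sa < th.sumQS
    return {
        ROW_QS_FROM_INIT: quiet,
        ROW_QS_FROM_TERM: quiet
        and abs(gyroL) < th.minG
        and abs(gyroR) < th.minG,
        ROW_INITIATION: gd > th.init1
        and (grfL < th.QSgrf or grfR < th.QSgrf)
        and sa > th.sumAngInit,
        ROW_TERMINATION: gd < th.init1
        and grfL > th.QSgrf
        and grfR > th.QSgrf
        and sa < th.sumAngTerm
        and abs(gyroL) < th.termG
        and abs(gyroR) < th.termG,
        ROW_LEFT_STANCE: gd > th.init1
        and sa > th.sumAngInit
        and grfL > th.stanceL
        and grfR < th.stanceR,
        ROW_LR_DOUBLE: grfR > th.stanceR
        and grfL > th.stanceL
        and copyL < th.midCOP
        and copyR > th.toeCOP
        and sa > th.minAng,
        ROW_RIGHT_STANCE: gd > th.init1
        and sa > th.sumAngInit
        and grfL < th.stanceL
        and grfR > th.stanceR,
        ROW_RL_DOUBLE: grfR > th.stanceR
        and grfL > th.stanceL
        and copyL > th.toeCOP
        and copyR < th.midCOP
        and sa > th.minAng,
    }


def eval_rows(
    frame: SensorFrame, derived: DerivedSignals, th: ThresholdSet
) -> set[PhaseFlag]:
    """Flags of every condition row satisfied by the frame (no state context)."""
    fired = eval_row_conditions(frame, derived, th)
    return {ROW_FLAG[row] for row, ok in fired.items() if ok}


def next_flag(
    current: PhaseFlag, fired: Mapping[str, bool], mode: str = "free"
) -> PhaseFlag:
    """Transition function: the flag after one sample given the fired rows.

    Returns ``current`` unchanged when no applicable row fires (free
    mode) or when every firing row proposes a transition that the state
    diagram forbids (strict mode).
    """
    if mode not in ("free", "strict"):
        raise ValueError(f"unknown detector mode: {mode!r}")
    for row in ROW_PRIORITY:
        if not fired.get(row, False):
            continue
        flag = ROW_FLAG[row]
        if mode == "free":
            if current in ROW_SOURCES[row]:
                return flag
        else:
            if flag == current or flag in TOPOLOGY[current]:
                return flag
    return current


@dataclass
class DetectorState:
    """Online detector state: current flag plus rolling GRF buffers."""

    current: PhaseFlag = PhaseFlag.UNKNOWN
    mode: str = "free"
    grfL_buf: deque = field(default_factory=lambda: deque(maxlen=GRF_DIFF_WINDOW))
    grfR_buf: deque = field(default_factory=lambda: deque(maxlen=GRF_DIFF_WINDOW))

    def derive(self, frame: SensorFrame) -> DerivedSignals:
        """Push the frame into the buffers and compute the derived signals."""
        self.grfL_buf.append(frame.grfL)
        self.grfR_buf.append(frame.grfR)
        return DerivedSignals(
            grfDiff=grf_diff(list(self.grfL_buf), list(self.grfR_buf)),
            sumAng=sum_ang(frame.hipL, frame.hipR, frame.kneeL, frame.kneeR),
        )


def step(
    state: DetectorState,
    frame: SensorFrame,
    th: ThresholdSet,
    derived: DerivedSignals | None = None,
) -> PhaseFlag:
    """Advance the online detector by one sample and return the new flag.

    When *derived* is given it is used as-is (the caller guarantees it
    matches the frame); otherwise the state's rolling buffers are updated
    with the frame and grfDiff/sumAng are computed from them.
    """
    if derived is None:
        derived = state.derive(frame)
    fired = eval_row_conditions(frame, derived, th)
    state.current = next_flag(state.current, fired, state.mode)
    return state.current


def _conditions_batch(trial: LabeledTrial, th: ThresholdSet) -> dict[str, np.ndarray]:
    """Vectorised row conditions for a whole trial (one bool array per row)."""
    grfL, grfR = trial.grfL, trial.grfR
    copyL, copyR = trial.copyL, trial.copyR
    gyroL, gyroR = np.abs(trial.gyroL), np.abs(trial.gyroR)
    sa = trial.sum_ang
    gd = grf_diff_series(grfL, grfR)

    quiet = (gd < th.init2) & (sa < th.sumQS)
    # NaN COP compares False, matching the scalar path.
    with np.errstate(invalid="ignore"):
        return {
            ROW_QS_FROM_INIT: quiet,
            ROW_QS_FROM_TERM: quiet & (gyroL < th.minG) & (gyroR < th.minG),
            ROW_INITIATION: (gd > th.init1)
            & ((grfL < th.QSgrf) | (grfR < th.QSgrf))
            & (sa > th.sumAngInit),
            ROW_TERMINATION: (gd < th.init1)
            & (grfL > th.QSgrf)
            & (grfR > th.QSgrf)
            & (sa < th.sumAngTerm)
            & (gyroL < th.termG)
            & (gyroR < th.termG),
            ROW_LEFT_STANCE: (gd > th.init1)
            & (sa > th.sumAngInit)
            & (grfL > th.stanceL)
            & (grfR < th.stanceR),
            ROW_LR_DOUBLE: (grfR > th.stanceR)
            & (grfL > th.stanceL)
            & (copyL < th.midCOP)
            & (copyR > th.toeCOP)
            & (sa > th.minAng),
            ROW_RIGHT_STANCE: (gd > th.init1)
            & (sa > th.sumAngInit)
            & (grfL < th.stanceL)
            & (grfR > th.stanceR),
            ROW_RL_DOUBLE: (grfR > th.stanceR)
            & (grfL > th.stanceL)
            & (copyL > th.toeCOP)
            & (copyR < th.midCOP)
            & (sa > th.minAng),
        }


def detect_trial(
    trial: LabeledTrial | Iterable[SensorFrame],
    th: ThresholdSet,
    mode: str = "free",
    validate: bool = True,
) -> np.ndarray:
    """Run the rule-based detector over a whole trial.

    Returns one PhaseFlag value per input sample.  The output is causal:
    the flag at sample ``i`` depends only on samples ``<= i``, and
    feeding the frames one by one through :func:`step` yields the exact
    same sequence.
    """
    if not isinstance(trial, LabeledTrial):
        trial = _trial_from_frames(trial)
    if validate:
        trial.validate_rate()
    n = len(trial)
    out = np.empty(n, dtype=int)
    if n == 0:
        return out
    conds = _conditions_batch(trial, th)
    rows = list(ROW_PRIORITY)
    cond_mat = {row: conds[row] for row in rows}
    current = PhaseFlag.UNKNOWN
    for i in range(n):
        fired = {row: bool(cond_mat[row][i]) for row in rows}
        current = next_flag(current, fired, mode)
        out[i] = int(current)
    return out


def _trial_from_frames(frames: Iterable[SensorFrame]) -> LabeledTrial:
    frames = list(frames)
    cols = {
        name: np.array([getattr(f, name) for f in frames], dtype=float)
        for name in (
            "t",
            "grfL",
            "grfR",
            "copyL",
            "copyR",
            "hipL",
            "hipR",
            "kneeL",
            "kneeR",
            "gyroL",
            "gyroR",
        )
    }
    return LabeledTrial(**cols)
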