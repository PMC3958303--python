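"""Success-ratio scoring, sequence checking and sound/prosthetic mapping.

A detector's per-sample flag stream is run-length encoded into walking
phase segments.  A ground-truth phase counts as correctly recognised
when some detected segment of the same flag overlaps it in time *and*
that segment sits in a locally consistent place in the stride cycle
(its neighbours precede/follow it in the cyclic order 11 -> 12 -> 13 ->
14 -> 11, with one skipped phase allowed, since the detector is free to
skip a phase it misses).  The success ratio of a phase type is the
number of correctly recognised phases over the number of all
ground-truth phases of that type, in percent.

For comparison across subjects, phases are reported by body side
relative to the prosthesis: SS_s / SS_p are the sound- and
prosthetic-leg single stances and DS_sp / DS_ps the double stances named
trailing-to-leading limb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import WALKING_FLAGS, PhaseFlag, SidePhase

#: Cyclic successor in the steady stride.
_NEXT = {
    PhaseFlag.LEFT_STANCE: PhaseFlag.LR_DOUBLE,
    PhaseFlag.LR_DOUBLE: PhaseFlag.RIGHT_STANCE,
    PhaseFlag.RIGHT_STANCE: PhaseFlag.RL_DOUBLE,
    PhaseFlag.RL_DOUBLE: PhaseFlag.LEFT_STANCE,
}


@dataclass(frozen=True)
class PhaseSegment:
    """A maximal run of one walking flag over samples [start, end)."""

    flag: PhaseFlag
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have end > start")

    def overlaps(self, other: "PhaseSegment") -> bool:
        return self.start < other.end and other.start < self.end


def segment_phases(
    flags: Sequence[int] | np.ndarray, debounce: int = 3
) -> list[PhaseSegment]:
    """Run-length encode a flag sequence into walking-phase segments.

    Non-walking flags (quiet standing, initiation, termination, unknown)
    are dropped.  Runs shorter than *debounce* samples are treated as
    detector chatter and absorbed into the longer adjacent walking
    segment (ties go to the earlier one); adjacent equal-flag segments
    are then coalesced.  ``debounce=0`` disables the filter.
    """
    flags = np.asarray(flags, dtype=int)
    if flags.size == 0:
        return []
    walking = {int(f) for f in WALKING_FLAGS}
    # raw RLE over the full stream: [flag, start, end]
    change = np.flatnonzero(np.diff(flags)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flags.size]))
    runs = [[int(flags[s]), int(s), int(e)] for s, e in zip(starts, ends)]

    def coalesce(items: list[list[int]]) -> list[list[int]]:
        out: list[list[int]] = []
        for flag, s, e in items:
            if out and out[-1][0] == flag:
                out[-1][2] = e
            else:
                out.append([flag, s, e])
        return out

    if debounce > 1:
        # Debounce on the full stream, so that a short non-walking blip
        # inside a walking phase is absorbed rather than splitting it.
        changed = True
        while changed:
            changed = False
            runs = coalesce(runs)
            if len(runs) < 2:
                break
            for i, (flag, s, e) in enumerate(runs):
                if e - s >= debounce:
                    continue
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i + 1 < len(runs) else None
                if right is None or (
                    left is not None and (left[2] - left[1]) >= (right[2] - right[1])
                ):
                    runs[i][0] = left[0]
                else:
                    runs[i][0] = right[0]
                changed = True
                break
        runs = coalesce(runs)
    return [
        PhaseSegment(PhaseFlag(flag), s, e) for flag, s, e in runs if flag in walking
    ]


def map_to_side(flag: PhaseFlag, prosthetic_side: str) -> SidePhase:
    """Map a walking flag to its sound/prosthetic phase name.

    With a right-side prosthesis the left single stance is the sound
    single stance; the L-R double stance (left trailing) is then DS_sp.
    The mapping mirrors for a left-side prosthesis and is a bijection
    for either side.
    """
    flag = PhaseFlag(flag)
    if flag not in _NEXT:
        raise ValueError(f"{flag!r} is not a walking phase")
    if prosthetic_side == "right":
        table = {
            PhaseFlag.LEFT_STANCE: SidePhase.SS_s,
            PhaseFlag.LR_DOUBLE: SidePhase.DS_sp,
            PhaseFlag.RIGHT_STANCE: SidePhase.SS_p,
            PhaseFlag.RL_DOUBLE: SidePhase.DS_ps,
        }
    elif prosthetic_side == "left":
        table = {
            PhaseFlag.LEFT_STANCE: SidePhase.SS_p,
            PhaseFlag.LR_DOUBLE: SidePhase.DS_ps,
            PhaseFlag.RIGHT_STANCE: SidePhase.SS_s,
            PhaseFlag.RL_DOUBLE: SidePhase.DS_sp,
        }
    else:
        raise ValueError("prosthetic_side must be 'left' or 'right'")
    return table[flag]


def sequence_check(
    flags: Sequence[int] | np.ndarray, skip_one: bool = True
) -> list[tuple[int, PhaseFlag, PhaseFlag]]:
    """Report state transitions that the gait state diagram forbids.

    Returns ``(sample_index, from_flag, to_flag)`` for every violating
    transition; an empty list means the sequence is valid.  With
    ``skip_one`` (the default) a single skipped walking phase is allowed
    (e.g. 11 -> 13); under ``skip_one=False`` only direct state-diagram
    transitions pass.  UNKNOWN samples before the first classification
    are ignored.
    """
    flags = np.asarray(flags, dtype=int)
    allowed: dict[PhaseFlag, set[PhaseFlag]] = {
        PhaseFlag.QUIET_STANDING: {PhaseFlag.INITIATION},
        PhaseFlag.INITIATION: {
            PhaseFlag.QUIET_STANDING,
            PhaseFlag.LEFT_STANCE,
            PhaseFlag.RIGHT_STANCE,
        },
        PhaseFlag.TERMINATION: {PhaseFlag.QUIET_STANDING},
        PhaseFlag.LEFT_STANCE: {PhaseFlag.LR_DOUBLE},
        PhaseFlag.LR_DOUBLE: {PhaseFlag.RIGHT_STANCE, PhaseFlag.TERMINATION},
        PhaseFlag.RIGHT_STANCE: {PhaseFlag.RL_DOUBLE},
        PhaseFlag.RL_DOUBLE: {PhaseFlag.LEFT_STANCE, PhaseFlag.TERMINATION},
    }
    if skip_one:
        for flag in WALKING_FLAGS:
            allowed[flag] = allowed[flag] | {_NEXT[_NEXT[flag]]}
    violations: list[tuple[int, PhaseFlag, PhaseFlag]] = []
    prev: PhaseFlag | None = None
    for i, raw in enumerate(flags):
        cur = PhaseFlag(int(raw))
        if cur == PhaseFlag.UNKNOWN:
            prev = None
            continue
        if prev is not None and cur != prev and cur not in allowed.get(prev, set()):
            violations.append((i, prev, cur))
        prev = cur
    return violations


@dataclass
class PhaseScore:
    """Counts and ratio for one side-mapped phase type."""

    n_true: int = 0
    n_correct: int = 0

    @property
    def ratio(self) -> float:
        """Success ratio in percent (NaN when no truth phases exist)."""
        if self.n_true == 0:
            return float("nan")
        return 100.0 * self.n_correct / self.n_true


@dataclass
class SuccessReport:
    """Per-phase detection success ratios for one or more trials."""

    scores: dict[SidePhase, PhaseScore] = field(
        default_factory=lambda: {ph: PhaseScore() for ph in SidePhase}
    )

    @property
    def mean(self) -> float:
        """Arithmetic mean of the four per-phase ratios (percent)."""
        ratios = [s.ratio for s in self.scores.values() if s.n_true > 0]
        return float(np.mean(ratios)) if ratios else float("nan")

    @property
    def mean_weighted(self) -> float:
        """Phase-count-weighted mean: pooled correct over pooled truth."""
        n_true = sum(s.n_true for s in self.scores.values())
        n_correct = sum(s.n_correct for s in self.scores.values())
        return 100.0 * n_correct / n_true if n_true else float("nan")

    def merge(self, other: "SuccessReport") -> "SuccessReport":
        """Pool counts with another report (ratio of pooled counts)."""
        out = SuccessReport()
        for ph in SidePhase:
            out.scores[ph] = PhaseScore(
                n_true=self.scores[ph].n_true + other.scores[ph].n_true,
                n_correct=self.scores[ph].n_correct + other.scores[ph].n_correct,
            )
        return out

    def to_dict(self) -> dict:
        return {
            "phases": {
                ph.value: {
                    "n_true": s.n_true,
                    "n_correct": s.n_correct,
                    "ratio": s.ratio,
                }
                for ph, s in self.scores.items()
            },
            "mean": self.mean,
            "mean_weighted": self.mean_weighted,
        }


def _locally_consistent(segs: list[PhaseSegment], i: int) -> bool:
    """Neighbours of segment i follow the cyclic order (one skip allowed)."""
    seg = segs[i]
    if i > 0:
        prev = segs[i - 1].flag
        if seg.flag not in (_NEXT[prev], _NEXT[_NEXT[prev]]):
            return False
    if i + 1 < len(segs):
        nxt = segs[i + 1].flag
        if nxt not in (_NEXT[seg.flag], _NEXT[_NEXT[seg.flag]]):
            return False
    return True


def success_ratio(
    detected: list[PhaseSegment],
    truth: list[PhaseSegment],
    prosthetic_side: str = "right",
) -> SuccessReport:
    """Score detected walking segments against ground-truth segments.

    A truth phase is correct when a same-flag detected segment overlaps
    it and that detected segment's immediate neighbours are consistent
    with the stride cycle (one skipped phase allowed).  Ratios are
    reported per sound/prosthetic-mapped phase type in percent.

    Raises
    ------
    ValueError
        If *truth* contains no walking segments.
    """
    if not truth:
        raise ValueError("truth segmentation is empty; nothing to score")
    report = SuccessReport()
    consistent = [_locally_consistent(detected, i) for i in range(len(detected))]
    for t in truth:
        side_phase = map_to_side(t.flag, prosthetic_side)
        score = report.scores[side_phase]
        score.n_true += 1
        for i, d in enumerate(detected):
            if d.flag == t.flag and d.overlaps(t) and consistent[i]:
                score.n_correct += 1
                break
    return report


def pool_reports(reports: Iterable[SuccessReport]) -> SuccessReport:
    """Pool per-trial reports by summing counts (order-invariant)."""
    out = SuccessReport()
    for r in reports:
        out = out.merge(r)
    return out
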