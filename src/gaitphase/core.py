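"""Core domain types, derived signals and trial / threshold-config I/O.

All signals follow the wearable-sensor convention used throughout the
package: vertical ground reaction forces (GRF) per foot in newtons,
longitudinal centre of pressure (COP) per foot in millimetres with the
origin at the toes and values increasing toward the heel, hip/knee
flexion angles in degrees, and sagittal-plane foot angular velocity in
rad/s.  Trials are sampled at a fixed 100 Hz; a mismatched sampling rate
is a validation error, not something the package resamples.

A foot that carries no load has no meaningful COP.  The package encodes
that with NaN (a reserved non-numeric sentinel, never a magic number in
the 0-300 mm range); every threshold comparison against a sentinel COP
evaluates to False.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SAMPLE_RATE_HZ = 100.0
#: Nominal spacing between consecutive samples (s).
SAMPLE_DT = 1.0 / SAMPLE_RATE_HZ
#: GRF below this value (N) means the foot is treated as unloaded and its
#: COP must be the sentinel.
CONTACT_EPS_N = 20.0
#: Window length (samples) of the rolling mean absolute GRF difference.
GRF_DIFF_WINDOW = 50
#: Default insole length (mm), toe (0) to heel.
INSOLE_LENGTH_MM = 260.0

#: NaN sentinel marking the COP of an unloaded foot.
COP_UNLOADED = float("nan")

TRIAL_COLUMNS = (
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
LABEL_COLUMN = "label"


class SchemaError(ValueError):
    """A trial file or config violates the documented schema."""


class PhaseFlag(enum.IntEnum):
    """Integer state labels emitted by the detectors.

    The four walking phases 11-14 cover one steady-state stride; 4-6 are
    the non-steady states bracketing the walking manoeuvre.  UNKNOWN is
    only ever seen before the first classified sample.
    """

    UNKNOWN = 0
    TERMINATION = 4
    QUIET_STANDING = 5
    INITIATION = 6
    LEFT_STANCE = 11
    LR_DOUBLE = 12
    RIGHT_STANCE = 13
    RL_DOUBLE = 14


#: The four steady-walking flags in cyclic stride order.
WALKING_FLAGS = (
    PhaseFlag.LEFT_STANCE,
    PhaseFlag.LR_DOUBLE,
    PhaseFlag.RIGHT_STANCE,
    PhaseFlag.RL_DOUBLE,
)


class SidePhase(enum.Enum):
    """Walking phases named by sound (s) / prosthetic (p) side.

    ``DS_sp`` is the double stance with the sound leg trailing and the
    prosthetic leg leading; ``DS_ps`` the mirror image.
    """

    SS_s = "SS_s"
    SS_p = "SS_p"
    DS_sp = "DS_sp"
    DS_ps = "DS_ps"


@dataclass(frozen=True)
class SensorFrame:
    """One 100 Hz sample of every input signal.

    COP fields hold :data:`COP_UNLOADED` (NaN) while the corresponding
    foot carries less than :data:`CONTACT_EPS_N`.
    """

    t: float
    grfL: float
    grfR: float
    copyL: float
    copyR: float
    hipL: float
    hipR: float
    kneeL: float
    kneeR: float
    gyroL: float
    gyroR: float

    def __post_init__(self) -> None:
        if self.grfL < 0 or self.grfR < 0:
            raise ValueError("ground reaction forces must be non-negative")


@dataclass(frozen=True)
class DerivedSignals:
    """Signals derived from the raw frame stream.

    grfDiff is the mean absolute left/right GRF difference over the past
    50 samples (a lateral-asymmetry measure); sumAng is the sum of both
    hip and both knee flexion angles (total lower-limb flexion).
    """

    grfDiff: float
    sumAng: float

    def __post_init__(self) -> None:
        if self.grfDiff < 0:
            raise ValueError("grfDiff is a mean of absolute values, must be >= 0")


def grf_diff(
    grfL_history: Sequence[float],
    grfR_history: Sequence[float],
    window: int = GRF_DIFF_WINDOW,
) -> float:
    """Mean absolute GRF difference over the most recent *window* samples.

    Histories shorter than the window are averaged over whatever is
    available (no zero padding, which would fake symmetry at start-up).

    Raises
    ------
    ValueError
        If the histories are empty or of unequal length.
    """
    a = np.asarray(grfL_history, dtype=float)
    b = np.asarray(grfR_history, dtype=float)
    if a.shape != b.shape:
        raise ValueError("GRF histories must have equal length")
    if a.size == 0:
        raise ValueError("cannot compute grfDiff from empty histories")
    n = min(int(window), a.size)
    if n < 1:
        raise ValueError("window must be >= 1")
    return float(np.mean(np.abs(a[-n:] - b[-n:])))


def sum_ang(hipL: float, hipR: float, kneeL: float, kneeR: float) -> float:
    """Total lower-limb flexion: the sum of all knee and hip angles (deg)."""
    return float(hipL + hipR + kneeL + kneeR)


def grf_diff_series(
    grfL: np.ndarray, grfR: np.ndarray, window: int = GRF_DIFF_WINDOW
) -> np.ndarray:
    """Causal rolling grfDiff for a whole trial.

    ``out[i]`` equals :func:`grf_diff` applied to the histories up to and
    including sample ``i``; the first samples use the shorter available
    history.
    """
    d = np.abs(np.asarray(grfL, float) - np.asarray(grfR, float))
    if d.size == 0:
        return d
    s = pd.Series(d)
    return s.rolling(window, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# Thresholds


THRESHOLD_NAMES = (
    "QSgrf",
    "stanceL",
    "stanceR",
    "init1",
    "init2",
    "sumQS",
    "sumAngInit",
    "sumAngTerm",
    "minAng",
    "midCOP",
    "toeCOP",
    "minG",
    "termG",
)

# Threshold fields that may legitimately be negative (joint-angle sums can
# be negative for hyperextended postures).
_ANGLE_THRESHOLDS = frozenset({"sumQS", "sumAngInit", "sumAngTerm", "minAng"})


@dataclass(frozen=True)
class ThresholdSet:
    """The 13 named detection thresholds.

    Forces in N, COP positions in mm (toe origin), angles in degrees,
    angular velocities in rad/s.  ``init1``/``init2`` bound the grfDiff
    asymmetry signal (``init2 <= init1``); ``toeCOP <= midCOP`` splits the
    insole into a toe region and the rest.
    """

    QSgrf: float
    stanceL: float
    stanceR: float
    init1: float
    init2: float
    sumQS: float
    sumAngInit: float
    sumAngTerm: float
    minAng: float
    midCOP: float
    toeCOP: float
    minG: float
    termG: float

    def __post_init__(self) -> None:
        for name in THRESHOLD_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"threshold {name} must be finite")
            if name not in _ANGLE_THRESHOLDS and v < 0:
                raise ValueError(f"threshold {name} must be >= 0")
        if self.init2 > self.init1:
            raise ValueError("init2 must not exceed init1")
        if self.toeCOP > self.midCOP:
            raise ValueError("toeCOP must not exceed midCOP")

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in THRESHOLD_NAMES}


def default_thresholds(
    body_weight: float = 600.0, insole_length: float = INSOLE_LENGTH_MM
) -> ThresholdSet:
    """Default thresholds scaled to body weight W (N) and insole length L (mm).

    These mirror the per-subject tuning the detector expects in practice:
    force thresholds are fractions of W, COP thresholds fractions of L.
    """
    W, L = float(body_weight), float(insole_length)
    return ThresholdSet(
        QSgrf=0.30 * W,
        stanceL=0.05 * W,
        stanceR=0.05 * W,
        init1=0.15 * W,
        init2=0.10 * W,
        sumQS=15.0,
        sumAngInit=25.0,
        sumAngTerm=20.0,
        minAng=10.0,
        midCOP=0.45 * L,
        toeCOP=0.30 * L,
        minG=0.2,
        termG=0.3,
    )


def thresholds_from_mapping(data: Mapping[str, float]) -> ThresholdSet:
    """Build a ThresholdSet from a plain mapping, rejecting unknown keys."""
    unknown = set(data) - set(THRESHOLD_NAMES)
    if unknown:
        raise SchemaError(f"unknown threshold keys: {sorted(unknown)}")
    missing = set(THRESHOLD_NAMES) - set(data)
    if missing:
        raise SchemaError(f"missing threshold keys: {sorted(missing)}")
    return ThresholdSet(**{k: float(v) for k, v in data.items()})


def read_thresholds(path: str | Path) -> ThresholdSet:
    """Read a threshold config from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise SchemaError("threshold config must be a mapping of name -> value")
    return thresholds_from_mapping(data)


def write_thresholds(th: ThresholdSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(th.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(th.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Trials


@dataclass
class LabeledTrial:
    """A sensor trial with optional per-sample ground-truth phase labels.

    Column-oriented storage: each signal is a float ndarray of equal
    length; ``labels`` (if present) is an int ndarray of PhaseFlag values.
    ``meta`` carries body weight, prosthetic side, seed and generator
    parameters for synthetic trials.
    """

    t: np.ndarray
    grfL: np.ndarray
    grfR: np.ndarray
    copyL: np.ndarray
    copyR: np.ndarray
    hipL: np.ndarray
    hipR: np.ndarray
    kneeL: np.ndarray
    kneeR: np.ndarray
    gyroL: np.ndarray
    gyroR: np.ndarray
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in TRIAL_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or len(arr) != n:
                raise SchemaError(f"column {name} must be 1-D of length {n}")
            setattr(self, name, arr)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != n:
                raise SchemaError("labels and frames must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise SchemaError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sum_ang(self) -> np.ndarray:
        return self.hipL + self.hipR + self.kneeL + self.kneeR

    def frame(self, i: int) -> SensorFrame:
        return SensorFrame(
            t=float(self.t[i]),
            grfL=float(self.grfL[i]),
            grfR=float(self.grfR[i]),
            copyL=float(self.copyL[i]),
            copyR=float(self.copyR[i]),
            hipL=float(self.hipL[i]),
            hipR=float(self.hipR[i]),
            kneeL=float(self.kneeL[i]),
            kneeR=float(self.kneeR[i]),
            gyroL=float(self.gyroL[i]),
            gyroR=float(self.gyroR[i]),
        )

    def frames(self) -> Iterable[SensorFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def validate_rate(self, rtol: float = 1e-3) -> None:
        """Raise SchemaError if the trial is not sampled at 100 Hz."""
        if len(self) < 2:
            return
        dt = np.diff(self.t)
        if not np.allclose(dt, SAMPLE_DT, rtol=rtol, atol=1e-6):
            raise SchemaError(
                "trial is not uniformly sampled at 100 Hz "
                f"(observed median dt = {np.median(dt):.6g} s)"
            )

    def to_dataframe(self) -> pd.DataFrame:
        data = {name: getattr(self, name) for name in TRIAL_COLUMNS}
        if self.labels is not None:
            data[LABEL_COLUMN] = self.labels
        return pd.DataFrame(data)


def trial_from_dataframe(df: pd.DataFrame, meta: dict | None = None) -> LabeledTrial:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial is missing columns: {missing}")
    labels = None
    if LABEL_COLUMN in df.columns and len(df):
        labels = df[LABEL_COLUMN].to_numpy(dtype=int)
    elif LABEL_COLUMN in df.columns:
        labels = np.zeros(0, dtype=int)
    kwargs = {name: df[name].to_numpy(dtype=float) for name in TRIAL_COLUMNS}
    return LabeledTrial(labels=labels, meta=dict(meta or {}), **kwargs)


def read_trial(path: str | Path) -> LabeledTrial:
    """Read a trial CSV (sentinel COP encoded as an empty field)."""
    # round_trip: the default fast parser loses the last ulp of a double
    df = pd.read_csv(path, float_precision="round_trip")
    return trial_from_dataframe(df)


def write_trial(trial: LabeledTrial, path: str | Path) -> None:
    """Write a trial CSV; NaN COP sentinels become empty fields."""
    trial.to_dataframe().to_csv(path, index=False)
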