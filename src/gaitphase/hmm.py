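"""Supervised per-phase hidden-Markov-model gait classifier.

One three-state HMM with diagonal-Gaussian emissions is trained per
walking phase (flags 11-14) by maximum-likelihood (Baum-Welch) on
labelled phase segments.  Online classification slides a window of the
current and past 9 samples over the feature stream, evaluates the
forward-algorithm log-likelihood of the window under each of the four
phase models, and emits the flag of the best model.  Quiet standing,
initiation and termination are not HMM classes; samples before the
first full window are UNKNOWN.

Features are the same signal combination the threshold rule engine
uses — both GRFs, the windowed GRF asymmetry, both COP positions, the
flexion sum and both foot angular velocities — plus one binary
"loaded" indicator per foot.  A sentinel (NaN) COP is replaced by the
mid-insole position so the vectors stay numeric; the loaded indicator
carries the contact information instead.  All features are z-scored
with location/scale estimated on the training set, so classification is
invariant to any common affine rescaling of the inputs.

Model fitting is delegated to :mod:`hmmlearn` (Baum-Welch with a
variance floor); window scoring uses this module's own log-space
forward recursion, which the test-suite cross-checks against both
hmmlearn and exhaustive hidden-path enumeration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.special import logsumexp

from .core import (
    INSOLE_LENGTH_MM,
    DerivedSignals,
    LabeledTrial,
    PhaseFlag,
    SensorFrame,
    WALKING_FLAGS,
    grf_diff_series,
)

FEATURE_NAMES = (
    "grfL",
    "grfR",
    "grfDiff",
    "copyL",
    "copyR",
    "sumAng",
    "gyroL",
    "gyroR",
    "loadedL",
    "loadedR",
)

#: Sliding-window length: the current and past 9 samples.
WINDOW = 10
#: Diagonal-covariance floor, in z-scored feature units: no state may
#: claim a standard deviation below 10% of a feature's training spread.
#: Clean synthetic segments are otherwise exactly constant in several
#: features, and the resulting near-singular Gaussians turn window
#: classification at phase boundaries into a lottery between equally
#: terrible models.
VAR_FLOOR = 1e-2
#: EM iteration cap and convergence tolerance on the total log-likelihood.
EM_MAX_ITER = 200
EM_TOL = 1e-6


def extract_features(
    frame: SensorFrame,
    derived: DerivedSignals,
    cop_fill: float = INSOLE_LENGTH_MM / 2.0,
) -> np.ndarray:
    """Raw (un-normalised) feature vector for one frame.

    Order is :data:`FEATURE_NAMES`.  A NaN COP becomes *cop_fill* with
    the corresponding loaded indicator set to 0.
    """
    loadedL = float(np.isfinite(frame.copyL))
    loadedR = float(np.isfinite(frame.copyR))
    return np.array(
        [
            frame.grfL,
            frame.grfR,
            derived.grfDiff,
            frame.copyL if loadedL else cop_fill,
            frame.copyR if loadedR else cop_fill,
            derived.sumAng,
            frame.gyroL,
            frame.gyroR,
            loadedL,
            loadedR,
        ]
    )


def trial_features(
    trial: LabeledTrial, cop_fill: float = INSOLE_LENGTH_MM / 2.0
) -> np.ndarray:
    """Raw feature matrix (n_samples, n_features) for a whole trial."""
    n = len(trial)
    loadedL = np.isfinite(trial.copyL)
    loadedR = np.isfinite(trial.copyR)
    out = np.column_stack(
        [
            trial.grfL,
            trial.grfR,
            grf_diff_series(trial.grfL, trial.grfR),
            np.where(loadedL, trial.copyL, cop_fill),
            np.where(loadedR, trial.copyR, cop_fill),
            trial.sum_ang,
            trial.gyroL,
            trial.gyroR,
            loadedL.astype(float),
            loadedR.astype(float),
        ]
    )
    assert out.shape == (n, len(FEATURE_NAMES))
    return out


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature location/scale (z-score) normalisation."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        mean = np.mean(x, axis=0)
        scale = np.std(x, axis=0)
        scale = np.where(scale < 1e-8, 1.0, scale)  # constant features pass through
        return cls(mean=mean, scale=scale)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.scale

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.scale + self.mean


@dataclass
class GaitHMM:
    """A three-state diagonal-Gaussian HMM for one walking phase.

    ``startprob`` and each row of ``transmat`` sum to one; ``covars``
    holds per-state diagonal variances floored at :data:`VAR_FLOOR`.
    ``fit_history`` records the per-iteration training log-likelihood.
    """

    phase: PhaseFlag
    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    covars: np.ndarray
    fit_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, float)
        self.transmat = np.asarray(self.transmat, float)
        self.means = np.asarray(self.means, float)
        self.covars = np.asarray(self.covars, float)
        if not np.allclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition-matrix rows must sum to 1")
        if np.any(self.covars < VAR_FLOOR * (1 - 1e-12)):
            raise ValueError("variances must respect the floor")

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    def emission_logprob(self, x: np.ndarray) -> np.ndarray:
        """log N(x_t | state) for all t, states: shape (T, n_states)."""
        x = np.atleast_2d(np.asarray(x, float))
        diff = x[:, None, :] - self.means[None, :, :]
        return -0.5 * np.sum(
            diff * diff / self.covars[None, :, :]
            + np.log(2.0 * np.pi * self.covars)[None, :, :],
            axis=2,
        )

    def log_likelihood(self, x: np.ndarray) -> float:
        """Forward-algorithm log-likelihood of an observation sequence."""
        logb = self.emission_logprob(x)
        return _log_forward(self.startprob, self.transmat, logb)

    def to_dict(self) -> dict:
        return {
            "phase": int(self.phase),
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitHMM":
        return cls(
            phase=PhaseFlag(d["phase"]),
            startprob=np.array(d["startprob"]),
            transmat=np.array(d["transmat"]),
            means=np.array(d["means"]),
            covars=np.array(d["covars"]),
        )


def _log_forward(
    startprob: np.ndarray, transmat: np.ndarray, logb: np.ndarray
) -> float:
    """Log-space forward recursion; tolerates structural zeros."""
    with np.errstate(divide="ignore"):
        log_start = np.log(startprob)
        log_trans = np.log(transmat)
    alpha = log_start + logb[0]
    for t in range(1, len(logb)):
        alpha = logsumexp(alpha[:, None] + log_trans, axis=0) + logb[t]
    return float(logsumexp(alpha))


def train_phase_hmm(
    segments: Sequence[np.ndarray],
    phase: PhaseFlag = PhaseFlag.LEFT_STANCE,
    n_states: int = 3,
    seed: int = 0,
) -> GaitHMM:
    """Baum-Welch fit of one phase model on (normalised) feature segments.

    Initialisation is deterministic: emission means/variances from a
    partition of every segment into ``n_states`` temporal thirds, a
    left-to-right transition prior with self-loops, and all start mass
    on the first state.  Constant segments are handled by the variance
    floor.  Same seed and data give an identical model.

    Raises
    ------
    ValueError
        Without at least one segment of length >= ``n_states``.
    """
    segments = [np.atleast_2d(np.asarray(s, float)) for s in segments]
    if not segments or min(len(s) for s in segments) < n_states:
        raise ValueError(f"need >= 1 segment, each of length >= {n_states}")
    d = segments[0].shape[1]

    # temporal-thirds initial emissions
    means = np.zeros((n_states, d))
    covars = np.zeros((n_states, d))
    for k in range(n_states):
        chunks = [s[len(s) * k // n_states : len(s) * (k + 1) // n_states] for s in segments]
        data = np.concatenate([c for c in chunks if len(c)], axis=0)
        means[k] = data.mean(axis=0)
        covars[k] = np.maximum(data.var(axis=0), VAR_FLOOR)
    transmat = np.zeros((n_states, n_states))
    for k in range(n_states):
        if k + 1 < n_states:
            transmat[k, k], transmat[k, k + 1] = 0.9, 0.1
        else:
            transmat[k, k] = 1.0
    startprob = np.zeros(n_states)
    startprob[0] = 1.0

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        min_covar=VAR_FLOOR,
        n_iter=EM_MAX_ITER,
        tol=EM_TOL,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = startprob
    model.transmat_ = transmat
    model.means_ = means.copy()
    model.covars_ = covars.copy()
    x = np.concatenate(segments, axis=0)
    lengths = [len(s) for s in segments]
    # The variance-floor term in the M-step can shrink the raw likelihood
    # by ~1e-5 on near-degenerate features; hmmlearn's monitor logs a
    # "not converging" warning for that, which is noise here.
    hmmlearn_log = logging.getLogger("hmmlearn.base")
    level = hmmlearn_log.level
    hmmlearn_log.setLevel(logging.ERROR)
    try:
        model.fit(x, lengths)
    finally:
        hmmlearn_log.setLevel(level)

    startprob_ = np.clip(model.startprob_, 0.0, None)
    transmat_ = np.clip(model.transmat_, 0.0, None)
    startprob_ = startprob_ / startprob_.sum()
    transmat_ = transmat_ / transmat_.sum(axis=1, keepdims=True)
    covars_ = np.asarray(model.covars_)
    if covars_.ndim == 3:  # hmmlearn reports 'diag' covariances as full matrices
        covars_ = covars_.diagonal(axis1=1, axis2=2)
    return GaitHMM(
        phase=PhaseFlag(phase),
        startprob=startprob_,
        transmat=transmat_,
        means=model.means_.copy(),
        covars=np.maximum(covars_, VAR_FLOOR),
        fit_history=list(model.monitor_.history),
    )


@dataclass
class HMMBank:
    """Four trained phase models sharing one feature definition and scaler."""

    models: dict[PhaseFlag, GaitHMM]
    scaler: FeatureScaler
    cop_fill: float = INSOLE_LENGTH_MM / 2.0

    def __post_init__(self) -> None:
        if set(self.models) != set(WALKING_FLAGS):
            raise ValueError("bank must hold exactly one model per walking flag")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_names": list(FEATURE_NAMES),
            "window": WINDOW,
            "cop_fill": self.cop_fill,
            "scaler": {
                "mean": self.scaler.mean.tolist(),
                "scale": self.scaler.scale.tolist(),
            },
            "models": {str(int(f)): m.to_dict() for f, m in self.models.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMBank":
        doc = json.loads(Path(path).read_text())
        return cls(
            models={
                PhaseFlag(int(k)): GaitHMM.from_dict(v)
                for k, v in doc["models"].items()
            },
            scaler=FeatureScaler(
                mean=np.array(doc["scaler"]["mean"]),
                scale=np.array(doc["scaler"]["scale"]),
            ),
            cop_fill=float(doc.get("cop_fill", INSOLE_LENGTH_MM / 2.0)),
        )


def _phase_segments(trial: LabeledTrial) -> dict[PhaseFlag, list[slice]]:
    """Contiguous runs of each walking flag in a labelled trial."""
    if trial.labels is None:
        raise ValueError("HMM training requires labelled trials")
    labels = trial.labels
    out: dict[PhaseFlag, list[slice]] = {f: [] for f in WALKING_FLAGS}
    walking = {int(f) for f in WALKING_FLAGS}
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if int(labels[i]) in walking:
            out[PhaseFlag(int(labels[i]))].append(slice(i, j))
        i = j
    return out


def train_bank(
    trials: Sequence[LabeledTrial],
    n_states: int = 3,
    seed: int = 0,
    cop_fill: float = INSOLE_LENGTH_MM / 2.0,
) -> HMMBank:
    """Train the four phase models from labelled trials.

    The feature scaler is fitted on all walking-phase samples of the
    training set and shared by the four models.
    """
    per_phase: dict[PhaseFlag, list[np.ndarray]] = {f: [] for f in WALKING_FLAGS}
    walking_rows = []
    feats = [trial_features(t, cop_fill) for t in trials]
    for trial, x in zip(trials, feats):
        for flag, slices in _phase_segments(trial).items():
            for sl in slices:
                if sl.stop - sl.start >= n_states:
                    per_phase[flag].append(x[sl])
                    walking_rows.append(x[sl])
    if not walking_rows:
        raise ValueError("training trials contain no walking-phase segments")
    scaler = FeatureScaler.fit(np.concatenate(walking_rows, axis=0))
    models = {}
    for flag in WALKING_FLAGS:
        segs = [scaler.normalize(s) for s in per_phase[flag]]
        if not segs:
            raise ValueError(f"no training segments for phase {flag.name}")
        models[flag] = train_phase_hmm(segs, phase=flag, n_states=n_states, seed=seed)
    return HMMBank(models=models, scaler=scaler, cop_fill=cop_fill)


def classify_window(window: np.ndarray, bank: HMMBank) -> PhaseFlag:
    """Flag of the phase model with maximal window log-likelihood.

    *window* holds :data:`WINDOW` consecutive raw feature vectors
    (oldest first); normalisation is applied here.  Ties break towards
    the lowest flag number (11 < 12 < 13 < 14).
    """
    window = np.asarray(window, float)
    if window.shape[0] != WINDOW:
        raise ValueError(f"window must hold exactly {WINDOW} samples")
    z = bank.scaler.normalize(window)
    best_flag, best_ll = None, -np.inf
    for flag in WALKING_FLAGS:  # fixed ascending order -> deterministic ties
        ll = bank.models[flag].log_likelihood(z)
        if ll > best_ll:
            best_flag, best_ll = flag, ll
    return best_flag


def detect_trial_hmm(
    trial: LabeledTrial, bank: HMMBank, validate: bool = True
) -> np.ndarray:
    """Sliding-window HMM classification of a whole trial.

    Causal: the flag at sample ``i`` uses samples ``i-9 .. i`` only.
    The first 9 samples (no full window yet) are UNKNOWN.
    """
    if validate:
        trial.validate_rate()
    n = len(trial)
    out = np.full(n, int(PhaseFlag.UNKNOWN), dtype=int)
    if n < WINDOW:
        return out
    z = bank.scaler.normalize(trial_features(trial, bank.cop_fill))
    flags = list(WALKING_FLAGS)
    logb = {f: bank.models[f].emission_logprob(z) for f in flags}
    for i in range(WINDOW - 1, n):
        lls = [
            _log_forward(
                bank.models[f].startprob,
                bank.models[f].transmat,
                logb[f][i - WINDOW + 1 : i + 1],
            )
            for f in flags
        ]
        out[i] = int(flags[int(np.argmax(lls))])
    return out


@dataclass(frozen=True)
class TrainTestSplit:
    """One training-set design: a name, the held-out subject (if any),
    and the train/test trial lists."""

    scheme: str
    subject: str | None
    train: tuple[LabeledTrial, ...]
    test: tuple[LabeledTrial, ...]


def build_training_sets(
    trials: Sequence[LabeledTrial], scheme: str, n_train: int = 3
) -> list[TrainTestSplit]:
    """Train/test splits for the three HMM evaluation designs.

    ``intra``: per subject, models trained on that subject's first
    *n_train* walks and tested on the rest.  ``inter``: per subject,
    models trained on the other subjects' training walks and tested on
    the held-out subject's test walks.  ``pooled``: one bank trained on
    every subject's training walks, tested on all remaining walks.
    Trials must carry ``meta['subject']``.
    """
    if n_train < 1:
        raise ValueError("need at least one training walk per subject")
    by_subject: dict[str, list[LabeledTrial]] = {}
    for t in trials:
        subj = t.meta.get("subject")
        if subj is None:
            raise ValueError("every trial needs meta['subject'] for splitting")
        by_subject.setdefault(str(subj), []).append(t)
    for subj, ts in by_subject.items():
        if len(ts) < n_train + 1:
            raise ValueError(
                f"subject {subj} has {len(ts)} trials; needs > {n_train} "
                "to train and still have test walks"
            )
    train_of = {s: tuple(ts[:n_train]) for s, ts in by_subject.items()}
    test_of = {s: tuple(ts[n_train:]) for s, ts in by_subject.items()}

    if scheme == "intra":
        return [
            TrainTestSplit("intra", s, train_of[s], test_of[s]) for s in by_subject
        ]
    if scheme == "inter":
        if len(by_subject) < 2:
            raise ValueError("inter-subject splitting needs >= 2 subjects")
        return [
            TrainTestSplit(
                "inter",
                s,
                tuple(t for o in by_subject if o != s for t in train_of[o]),
                test_of[s],
            )
            for s in by_subject
        ]
    if scheme == "pooled":
        return [
            TrainTestSplit(
                "pooled",
                None,
                tuple(t for s in by_subject for t in train_of[s]),
                tuple(t for s in by_subject for t in test_of[s]),
            )
        ]
    raise ValueError(f"unknown scheme {scheme!r}; use intra, inter or pooled")
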