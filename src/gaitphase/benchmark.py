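"""End-to-end synthetic benchmark of the detectors.

Draws a small population of synthetic subjects (each with their own body
weight, cadence, prosthetic side and asymmetry), simulates a set of
walks per subject with sensor noise, runs the configured detectors
(threshold rules and/or the HMM bank under its three training-set
designs) and scores per-phase success ratios per subject and pooled
over subjects.  Pooling sums phase counts rather than averaging
per-subject ratios, matching the definition of the success ratio over
all phases of a type.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabeledTrial, PhaseFlag, SidePhase, default_thresholds
from .evaluate import SuccessReport, pool_reports, segment_phases, success_ratio
from .hmm import build_training_sets, detect_trial_hmm, train_bank
from .rules import detect_trial
from .simulate import GaitParams, simulate_trial

DETECTORS = ("fsm", "hmm-intra", "hmm-inter", "hmm-pooled")

#: Ranges for per-subject parameter draws (uniform).
_SUBJECT_RANGES = {
    "body_weight": (520.0, 760.0),
    "stride_period": (0.9, 1.15),
    "asymmetry": (0.85, 0.95),
}


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study design for one benchmark run.

    Noise defaults are moderate wearable-sensor levels: GRF noise as a
    fraction of body weight, COP noise in mm, per-joint angle noise in
    degrees and gyro noise in rad/s.
    """

    n_subjects: int = 3
    walks_per_subject: int = 10
    n_train: int = 3
    n_strides: int = 10
    sigma_grf_frac: float = 0.02
    sigma_cop: float = 5.0
    sigma_ang: float = 2.0
    sigma_gyro: float = 0.05
    detectors: tuple[str, ...] = ("fsm",)
    seed: int = 1
    debounce: int = 3

    def __post_init__(self) -> None:
        if self.n_train >= self.walks_per_subject:
            raise ValueError("training walks must be fewer than total walks")
        unknown = set(self.detectors) - set(DETECTORS)
        if unknown:
            raise ValueError(f"unknown detectors: {sorted(unknown)}")
        if self.n_subjects < 2 and "hmm-inter" in self.detectors:
            raise ValueError("inter-subject HMM evaluation needs >= 2 subjects")


@dataclass
class Subject:
    subject_id: str
    side: str
    body_weight: float
    trials: list[LabeledTrial] = field(default_factory=list)


def make_subjects(config: BenchmarkConfig) -> list[Subject]:
    """Draw subjects and simulate their walks, deterministically in the seed.

    Trial seeds are consecutive integers (1, 2, ... for base seed 1), so
    every walk is individually reproducible.
    """
    subjects = []
    trial_counter = (config.seed - 1) * 100003
    for s in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, s])
        draws = {
            name: rng.uniform(*bounds) for name, bounds in _SUBJECT_RANGES.items()
        }
        side = "right" if s % 2 == 0 else "left"
        subject = Subject(
            subject_id=f"S{s + 1}", side=side, body_weight=draws["body_weight"]
        )
        for _ in range(config.walks_per_subject):
            trial_counter += 1
            params = GaitParams(
                n_strides=config.n_strides,
                prosthetic_side=side,
                sigma_grf=config.sigma_grf_frac * draws["body_weight"],
                sigma_cop=config.sigma_cop,
                sigma_ang=config.sigma_ang,
                sigma_gyro=config.sigma_gyro,
                seed=trial_counter,
                **draws,
            )
            trial = simulate_trial(params)
            trial.meta["subject"] = subject.subject_id
            subject.trials.append(trial)
        subjects.append(subject)
    return subjects


def _score_trial(
    trial: LabeledTrial, flags: np.ndarray, side: str, debounce: int
) -> SuccessReport:
    detected = segment_phases(flags, debounce=debounce)
    truth = segment_phases(trial.labels, debounce=0)
    return success_ratio(detected, truth, prosthetic_side=side)


def run_benchmark(config: BenchmarkConfig) -> dict[str, dict]:
    """Run every configured detector; return per-subject and pooled reports.

    Result layout: ``{detector: {"per_subject": {id: SuccessReport},
    "pooled": SuccessReport}}``.  The rule-based detector is evaluated on
    every walk; the HMM designs are evaluated on the walks outside their
    training sets.
    """
    subjects = make_subjects(config)
    side_of = {s.subject_id: s.side for s in subjects}
    results: dict[str, dict] = {}

    if "fsm" in config.detectors:
        per_subject = {}
        for subj in subjects:
            th = default_thresholds(subj.body_weight)
            reports = [
                _score_trial(
                    t, detect_trial(t, th), subj.side, config.debounce
                )
                for t in subj.trials
            ]
            per_subject[subj.subject_id] = pool_reports(reports)
        results["fsm"] = {
            "per_subject": per_subject,
            "pooled": pool_reports(per_subject.values()),
        }

    all_trials = [t for s in subjects for t in s.trials]
    for detector, scheme in (
        ("hmm-intra", "intra"),
        ("hmm-inter", "inter"),
        ("hmm-pooled", "pooled"),
    ):
        if detector not in config.detectors:
            continue
        per_subject: dict[str, SuccessReport] = {}
        for split in build_training_sets(all_trials, scheme, config.n_train):
            bank = train_bank(list(split.train), seed=config.seed)
            for t in split.test:
                subj = t.meta["subject"]
                report = _score_trial(
                    t, detect_trial_hmm(t, bank), side_of[subj], config.debounce
                )
                per_subject[subj] = (
                    per_subject[subj].merge(report) if subj in per_subject else report
                )
        results[detector] = {
            "per_subject": per_subject,
            "pooled": pool_reports(per_subject.values()),
        }
    return results


def results_table(results: dict[str, dict]) -> pd.DataFrame:
    """Flatten benchmark results into a tidy per-phase table (percent)."""
    rows = []
    for detector, res in results.items():
        entries = list(res["per_subject"].items()) + [("all", res["pooled"])]
        for subject, report in entries:
            row = {"detector": detector, "subject": subject}
            for ph in SidePhase:
                row[ph.value] = report.scores[ph].ratio
            row["mean"] = report.mean
            row["mean_weighted"] = report.mean_weighted
            rows.append(row)
    return pd.DataFrame(rows)


def results_to_dict(results: dict[str, dict]) -> dict:
    return {
        detector: {
            "per_subject": {
                s: r.to_dict() for s, r in res["per_subject"].items()
            },
            "pooled": res["pooled"].to_dict(),
        }
        for detector, res in results.items()
    }
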