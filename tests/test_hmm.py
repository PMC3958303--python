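"""The per-phase HMM classifier."""

import itertools
import math

import numpy as np
import pytest

from gaitphase import (
    DerivedSignals,
    GaitParams,
    PhaseFlag,
    SensorFrame,
    WALKING_FLAGS,
    build_training_sets,
    classify_window,
    extract_features,
    simulate_trial,
    train_bank,
    train_phase_hmm,
)
from gaitphase.hmm import (
    FEATURE_NAMES,
    FeatureScaler,
    GaitHMM,
    HMMBank,
    VAR_FLOOR,
    WINDOW,
    detect_trial_hmm,
    trial_features,
)


def toy_hmm(n_states=2):
    return GaitHMM(
        phase=PhaseFlag.LEFT_STANCE,
        startprob=np.array([0.6, 0.4]) if n_states == 2 else np.full(3, 1 / 3),
        transmat=np.array([[0.7, 0.3], [0.2, 0.8]])
        if n_states == 2
        else np.full((3, 3), 1 / 3),
        means=np.arange(n_states, dtype=float)[:, None] * 2.0,
        covars=np.full((n_states, 1), 0.8),
    )


def sample_known_hmm(rng, n_seqs=6, length=40):
    """Sequences from a known 3-state left-to-right Gaussian HMM."""
    means = np.array([[0.0, 0.0], [3.0, 1.0], [-1.0, 4.0]])
    segs = []
    for _ in range(n_seqs):
        state, seq = 0, []
        for _ in range(length):
            seq.append(rng.normal(means[state], 1.0))
            if state < 2 and rng.random() < 0.15:
                state += 1
        segs.append(np.array(seq))
    return segs


class TestFeatures:
    def test_order_and_sentinel_mapping(self):
        frame = SensorFrame(
            t=0.0, grfL=100.0, grfR=0.0, copyL=80.0, copyR=np.nan,
            hipL=5.0, hipR=5.0, kneeL=10.0, kneeR=10.0, gyroL=0.5, gyroR=-2.0,
        )
        derived = DerivedSignals(grfDiff=50.0, sumAng=30.0)
        x = extract_features(frame, derived, cop_fill=130.0)
        expected = [100.0, 0.0, 50.0, 80.0, 130.0, 30.0, 0.5, -2.0, 1.0, 0.0]
        np.testing.assert_allclose(x, expected)
        assert len(FEATURE_NAMES) == len(expected)

    def test_zero_signals_give_zero_features(self):
        frame = SensorFrame(
            t=0.0, grfL=0.0, grfR=0.0, copyL=0.0, copyR=0.0,
            hipL=0.0, hipR=0.0, kneeL=0.0, kneeR=0.0, gyroL=0.0, gyroR=0.0,
        )
        x = extract_features(frame, DerivedSignals(grfDiff=0.0, sumAng=0.0))
        np.testing.assert_allclose(x[:8], 0.0)

    def test_trial_features_match_per_frame_extraction(self, clean_trial):
        from gaitphase.core import grf_diff_series

        xs = trial_features(clean_trial)
        gd = grf_diff_series(clean_trial.grfL, clean_trial.grfR)
        for i in (0, len(clean_trial) // 2, len(clean_trial) - 1):
            xi = extract_features(
                clean_trial.frame(i),
                DerivedSignals(grfDiff=gd[i], sumAng=clean_trial.sum_ang[i]),
            )
            np.testing.assert_allclose(xs[i], xi)

    def test_scaler_round_trip(self, rng):
        x = rng.normal(5.0, 3.0, size=(100, 4))
        scaler = FeatureScaler.fit(x)
        np.testing.assert_allclose(scaler.denormalize(scaler.normalize(x)), x)

    def test_normalisation_absorbs_affine_rescaling(self, rng):
        x = rng.normal(size=(200, 5))
        y = x * np.array([2.0, 0.5, 10.0, 1.0, 3.0]) + 7.0
        zx = FeatureScaler.fit(x).normalize(x)
        zy = FeatureScaler.fit(y).normalize(y)
        np.testing.assert_allclose(zx, zy, atol=1e-10)


class TestTraining:
    def test_stochasticity_invariants(self, rng):
        model = train_phase_hmm(sample_known_hmm(rng), phase=PhaseFlag.LR_DOUBLE)
        np.testing.assert_allclose(model.startprob.sum(), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(model.covars >= VAR_FLOOR * (1 - 1e-12))

    def test_em_loglik_never_decreases(self, rng):
        model = train_phase_hmm(sample_known_hmm(rng))
        h = model.fit_history
        assert len(h) >= 2
        assert all(b - a >= -1e-8 for a, b in zip(h, h[1:]))
        assert h[-1] >= h[0]

    def test_same_seed_and_data_identical_model(self, rng):
        segs = sample_known_hmm(rng)
        a = train_phase_hmm(segs, seed=5)
        b = train_phase_hmm(segs, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.transmat, b.transmat)

    def test_constant_segments_hit_the_floor_without_failing(self):
        segs = [np.ones((20, 3)) for _ in range(3)]
        model = train_phase_hmm(segs)
        # occupied states collapse onto the floor; none may go below it
        np.testing.assert_allclose(model.covars[0], VAR_FLOOR)
        assert np.all(model.covars >= VAR_FLOOR * (1 - 1e-12))
        np.testing.assert_allclose(model.means[0], 1.0)

    def test_too_short_segments_rejected(self):
        with pytest.raises(ValueError):
            train_phase_hmm([np.ones((2, 3))])
        with pytest.raises(ValueError):
            train_phase_hmm([])


class TestForward:
    def test_matches_exhaustive_path_enumeration(self, rng):
        model = toy_hmm()
        x = rng.normal(size=(WINDOW, 1))
        logb = model.emission_logprob(x)
        total = -np.inf
        for path in itertools.product(range(2), repeat=len(x)):
            lp = math.log(model.startprob[path[0]]) + logb[0][path[0]]
            for t in range(1, len(x)):
                lp += math.log(model.transmat[path[t - 1], path[t]]) + logb[t][path[t]]
            total = np.logaddexp(total, lp)
        assert model.log_likelihood(x) == pytest.approx(total, abs=1e-8)

    def test_matches_hmmlearn_forward(self, rng):
        from hmmlearn.hmm import GaussianHMM

        model = toy_hmm()
        x = rng.normal(size=(WINDOW, 1))
        ref = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = model.startprob
        ref.transmat_ = model.transmat
        ref.means_ = model.means
        ref.covars_ = model.covars
        assert model.log_likelihood(x) == pytest.approx(ref.score(x), abs=1e-8)


@pytest.fixture(scope="module")
def small_bank():
    trials = []
    for seed in range(3):
        t = simulate_trial(GaitParams(n_strides=4, seed=seed))
        t.meta["subject"] = "S1"
        trials.append(t)
    return train_bank(trials), trials


class TestClassification:
    def test_identical_models_tie_break_to_lowest_flag(self):
        m = toy_hmm()
        bank = HMMBank(
            models={
                f: GaitHMM(f, m.startprob, m.transmat, m.means, m.covars)
                for f in WALKING_FLAGS
            },
            scaler=FeatureScaler(mean=np.zeros(1), scale=np.ones(1)),
        )
        window = np.zeros((WINDOW, 1))
        assert classify_window(window, bank) == PhaseFlag.LEFT_STANCE

    def test_wrong_window_length_rejected(self, small_bank):
        bank, _ = small_bank
        with pytest.raises(ValueError):
            classify_window(np.zeros((WINDOW - 1, len(FEATURE_NAMES))), bank)

    def test_windows_from_each_phase_classify_correctly(self, small_bank):
        bank, trials = small_bank
        held_out = simulate_trial(GaitParams(n_strides=4, seed=9))
        x = trial_features(held_out)
        runs = []
        pos = 0
        for value, group in itertools.groupby(held_out.labels):
            n = len(list(group))
            runs.append((int(value), pos, pos + n))
            pos += n
        for flag in WALKING_FLAGS:
            # a window fully inside one run of the phase
            start, end = next(
                (s, e) for v, s, e in runs if v == int(flag) and e - s > WINDOW
            )
            mid = (start + end) // 2
            window = x[mid - WINDOW + 1 : mid + 1]
            assert classify_window(window, bank) == flag

    def test_detection_is_unknown_before_first_full_window(self, small_bank):
        bank, trials = small_bank
        flags = detect_trial_hmm(trials[0], bank)
        assert set(flags[: WINDOW - 1].tolist()) == {int(PhaseFlag.UNKNOWN)}
        assert flags[WINDOW - 1] != int(PhaseFlag.UNKNOWN)

    def test_detection_is_causal(self, small_bank):
        from gaitphase.core import trial_from_dataframe

        bank, trials = small_bank
        trial = trials[0]
        full = detect_trial_hmm(trial, bank)
        n = len(trial) * 2 // 3
        half = detect_trial_hmm(
            trial_from_dataframe(trial.to_dataframe().iloc[:n]), bank
        )
        np.testing.assert_array_equal(full[:n], half)

    def test_empty_trial(self, small_bank):
        from gaitphase.core import trial_from_dataframe

        bank, trials = small_bank
        empty = trial_from_dataframe(trials[0].to_dataframe().iloc[:0])
        assert len(detect_trial_hmm(empty, bank)) == 0


class TestBankIO:
    def test_json_round_trip(self, small_bank, tmp_path):
        bank, trials = small_bank
        path = tmp_path / "bank.json"
        bank.to_json(path)
        back = HMMBank.from_json(path)
        flags_a = detect_trial_hmm(trials[0], bank)
        flags_b = detect_trial_hmm(trials[0], back)
        np.testing.assert_array_equal(flags_a, flags_b)

    def test_bank_requires_all_four_phases(self, small_bank):
        bank, _ = small_bank
        with pytest.raises(ValueError):
            HMMBank(
                models={PhaseFlag.LEFT_STANCE: bank.models[PhaseFlag.LEFT_STANCE]},
                scaler=bank.scaler,
            )


class TestTrainingSets:
    @pytest.fixture()
    def tagged_trials(self):
        trials = []
        for subj in ("A", "B", "C"):
            for walk in range(5):
                t = simulate_trial(GaitParams(n_strides=1, seed=walk))
                t.meta["subject"] = subj
                trials.append(t)
        return trials

    def test_intra_train_test_disjoint(self, tagged_trials):
        for split in build_training_sets(tagged_trials, "intra", n_train=3):
            assert not set(map(id, split.train)) & set(map(id, split.test))
            subjects = {t.meta["subject"] for t in split.train + split.test}
            assert subjects == {split.subject}

    def test_inter_excludes_the_verified_subject(self, tagged_trials):
        for split in build_training_sets(tagged_trials, "inter", n_train=3):
            assert split.subject not in {t.meta["subject"] for t in split.train}
            assert {t.meta["subject"] for t in split.test} == {split.subject}

    def test_pooled_is_a_single_bank_over_all_subjects(self, tagged_trials):
        (split,) = build_training_sets(tagged_trials, "pooled", n_train=3)
        assert {t.meta["subject"] for t in split.train} == {"A", "B", "C"}
        assert len(split.train) == 9

    def test_errors(self, tagged_trials):
        with pytest.raises(ValueError):
            build_training_sets(tagged_trials, "intra", n_train=0)
        with pytest.raises(ValueError):
            build_training_sets(tagged_trials, "intra", n_train=5)
        with pytest.raises(ValueError):
            build_training_sets(tagged_trials[:5], "inter", n_train=3)
        with pytest.raises(ValueError):
            build_training_sets(tagged_trials, "bogus")
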