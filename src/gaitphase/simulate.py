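"""Seeded synthetic gait-signal generator with analytic ground-truth labels.

The generator emulates the signal morphology of level walking recorded by
instrumented insoles and foot-mounted gyroscopes: a double-bump vertical
GRF during stance, a heel-to-toe COP progression, biphasic swing-phase
foot angular velocity, and a summed hip+knee flexion signal oscillating
between a small double-stance minimum and a large mid-swing maximum.
Every trial follows the same manoeuvre: quiet standing, gait initiation
(weight shift onto the trailing leg, first swing, first double stance),
``n_strides`` steady strides, termination, quiet standing.  Labels are
assigned analytically from the phase schedule, so the trials double as
ground truth for the detectors.

Waveform shapes (Gaussian-free cosine lobes for the GRF bump, a linear
COP ramp, a flat-topped / sharp-bottomed flexion oscillation, sinusoidal
swing gyro) are qualitative models of real morphology, parameterised so
tests can stress the detection thresholds.  Prosthetic-side asymmetry is
a plain amplitude and stance-time scaling; compensatory movement
patterns are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    CONTACT_EPS_N,
    INSOLE_LENGTH_MM,
    SAMPLE_RATE_HZ,
    DerivedSignals,
    LabeledTrial,
    PhaseFlag,
    SensorFrame,
    ThresholdSet,
)
from .rules import eval_rows

#: GRF double-bump shape constants: peaks ~1.1 W at 25% / 75% of stance,
#: valley ~0.8 W at mid-stance, with a 10%-of-stance edge ramp.
_GRF_BASE = 0.95
_GRF_BUMP = 0.15
_GRF_EDGE = 0.10

#: COP travels from 0.85 L (heel strike) to 0.10 L (toe off).
_COP_HEEL = 0.85
_COP_TOE = 0.10

#: Flexion-sum extremes (deg): double-stance minimum and mid-swing maximum.
_SUMANG_BASE = 3.0
_SUMANG_MIN = 5.0
_SUMANG_MAX = 70.0

#: Peak swing-phase foot angular velocity (rad/s).
_GYRO_AMP = 3.0

#: How the flexion sum is split across the four joint channels.
_JOINT_SHARES = {"hipL": 0.2, "hipR": 0.2, "kneeL": 0.3, "kneeR": 0.3}


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class GaitParams:
    """Study conditions for one synthetic walking trial.

    Defaults describe an unhurried able-bodied-like walk with a mild
    prosthetic-side asymmetry: body weight 600 N, 1 stride per second,
    per-leg stance fraction 0.62 with 0.12 of the stride spent in each
    double stance, and a 260 mm insole.  Noise levels are per-channel
    Gaussian standard deviations (N, mm, deg per joint, rad/s); they
    default to zero so that noise is an explicit choice of the caller.
    """

    body_weight: float = 600.0
    stride_period: float = 1.0
    n_strides: int = 10
    stance_fraction: float = 0.62
    ds_fraction: float = 0.12
    insole_length: float = INSOLE_LENGTH_MM
    prosthetic_side: str = "right"
    asymmetry: float = 0.9
    sigma_grf: float = 0.0
    sigma_cop: float = 0.0
    sigma_ang: float = 0.0
    sigma_gyro: float = 0.0
    quiet_before: float = 2.0
    quiet_after: float = 1.5
    weight_shift: float = 0.25
    first_swing: float = 0.35
    term_duration: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ds_fraction < 1.0 and 0.0 < self.stance_fraction < 1.0):
            raise ParameterError("stance and double-stance fractions must be in (0, 1)")
        if 2.0 * self.ds_fraction >= self.stance_fraction:
            raise ParameterError(
                "two double-stance periods cannot exceed the stance fraction"
            )
        # Alternating gait with no flight phase forces stance = 0.5 + DS.
        if abs(self.stance_fraction - (0.5 + self.ds_fraction)) > 1e-6:
            raise ParameterError(
                "stance_fraction must equal 0.5 + ds_fraction for an alternating "
                "gait with no flight phase"
            )
        if self.prosthetic_side not in ("left", "right", "none"):
            raise ParameterError("prosthetic_side must be 'left', 'right' or 'none'")
        if not (0.0 < self.asymmetry <= 1.0):
            raise ParameterError("asymmetry must be in (0, 1]")
        for name in ("sigma_grf", "sigma_cop", "sigma_ang", "sigma_gyro"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.n_strides < 1:
            raise ParameterError("n_strides must be >= 1")
        if self.body_weight <= 0 or self.stride_period <= 0 or self.insole_length <= 0:
            raise ParameterError("weight, stride period and insole length must be > 0")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _stance_grf(s: np.ndarray, weight: float, scale: float) -> np.ndarray:
    """Double-bump stance GRF at normalised stance time ``s`` in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    ramp = np.clip(np.minimum(s, 1.0 - s) / _GRF_EDGE, 0.0, 1.0)
    return scale * weight * ramp * (_GRF_BASE - _GRF_BUMP * np.cos(4.0 * np.pi * s))


def _stance_cop(s: np.ndarray, length: float) -> np.ndarray:
    """Linear heel-to-toe COP ramp at normalised stance time ``s``."""
    s = np.clip(s, 0.0, 1.0)
    return length * (_COP_HEEL - (_COP_HEEL - _COP_TOE) * s)


def _fill_anchor_curve(out: np.ndarray, anchors: list[tuple[int, float]]) -> None:
    """Fill ``out`` by interpolating between (index, value) anchors.

    Rising segments follow ``(0.5 - 0.5 cos(pi u))**0.5`` (sharp bottom,
    flat top) and falling segments its mirror image, which concentrates
    the flexion minima into narrow valleys at the double stances the way
    real flexion-sum traces do.
    """
    for (i0, v0), (i1, v1) in zip(anchors[:-1], anchors[1:]):
        if i1 <= i0:
            continue
        u = np.arange(i0, min(i1, len(out)))
        if len(u) == 0:
            continue
        x = (u - i0) / (i1 - i0)
        if v1 == v0:
            out[u] = v0
        elif v1 > v0:
            out[u] = v0 + (v1 - v0) * np.sqrt(0.5 - 0.5 * np.cos(np.pi * x))
        else:
            out[u] = v1 + (v0 - v1) * np.sqrt(0.5 + 0.5 * np.cos(np.pi * x))
    if anchors:
        last_i, last_v = anchors[-1]
        if last_i < len(out):
            out[last_i:] = last_v


def simulate_trial(params: GaitParams) -> LabeledTrial:
    """Generate one labelled synthetic walking trial at 100 Hz.

    The trial starts from quiet standing, initiates gait with the left
    leg (weight shift onto the right, left swing, first double stance —
    all labelled initiation), walks ``n_strides`` steady strides labelled
    cyclically left stance (11), L-R double stance (12), right stance
    (13), R-L double stance (14), then terminates and stands.  Same seed,
    same parameters: bit-identical output.
    """
    p = params
    fs = SAMPLE_RATE_HZ
    W, L, T = p.body_weight, p.insole_length, p.stride_period

    dsd = p.ds_fraction * T
    ss_total = T - 2.0 * dsd
    if p.prosthetic_side == "right":
        ssR = ss_total * p.asymmetry / (1.0 + p.asymmetry)
        ssL = ss_total - ssR
    elif p.prosthetic_side == "left":
        ssL = ss_total * p.asymmetry / (1.0 + p.asymmetry)
        ssR = ss_total - ssL
    else:
        ssL = ssR = ss_total / 2.0
    stride = ssL + dsd + ssR + dsd

    amp_l = p.asymmetry if p.prosthetic_side == "left" else 1.0
    amp_r = p.asymmetry if p.prosthetic_side == "right" else 1.0

    # --- timeline (seconds) ---------------------------------------------
    q1_end = p.quiet_before
    ws_end = q1_end + p.weight_shift  # weight fully on the right leg
    sw_end = ws_end + p.first_swing  # first (left) swing ends: heel strike
    walk_start = sw_end + dsd  # right toe-off: first left single stance
    walk_end = walk_start + p.n_strides * stride
    term_end = walk_end + p.term_duration
    t_total = term_end + p.quiet_after

    def I(t: float) -> int:
        return int(round(t * fs))

    n = I(t_total)
    t = np.arange(n) / fs
    idx = np.arange(n)

    grfL = np.zeros(n)
    grfR = np.zeros(n)
    copL = np.full(n, np.nan)
    copR = np.full(n, np.nan)
    gyroL = np.zeros(n)
    gyroR = np.zeros(n)
    labels = np.full(n, int(PhaseFlag.QUIET_STANDING))

    def stride_start(k: int) -> float:
        return walk_start + k * stride

    # --- labels ----------------------------------------------------------
    labels[I(q1_end) : I(walk_start)] = int(PhaseFlag.INITIATION)
    for k in range(p.n_strides):
        s0 = stride_start(k)
        labels[I(s0) : I(s0 + ssL)] = int(PhaseFlag.LEFT_STANCE)
        labels[I(s0 + ssL) : I(s0 + ssL + dsd)] = int(PhaseFlag.LR_DOUBLE)
        labels[I(s0 + ssL + dsd) : I(s0 + ssL + dsd + ssR)] = int(
            PhaseFlag.RIGHT_STANCE
        )
        labels[I(s0 + ssL + dsd + ssR) : I(s0 + stride)] = int(PhaseFlag.RL_DOUBLE)
    labels[I(walk_end) : I(term_end)] = int(PhaseFlag.TERMINATION)
    labels[I(term_end) :] = int(PhaseFlag.QUIET_STANDING)

    # --- standing / initiation GRF and COP -------------------------------
    sl = slice(0, I(q1_end))
    grfL[sl] = 0.5 * W
    grfR[sl] = 0.5 * W
    copL[sl] = 0.5 * L
    copR[sl] = 0.55 * L

    sl = slice(I(q1_end), I(ws_end))  # weight shift onto the right leg
    u = (t[sl] - q1_end) / p.weight_shift
    grfL[sl] = 0.5 * W * (1.0 - _smoothstep(u))
    grfR[sl] = W - grfL[sl]
    copL[sl] = 0.5 * L
    copR[sl] = 0.55 * L

    sl = slice(I(ws_end), I(sw_end))  # left swing, right single support
    grfR[sl] = W
    copR[sl] = 0.55 * L

    sl = slice(I(sw_end), I(walk_start))  # first double stance (initiation)
    u = (t[sl] - sw_end) / dsd
    grfR[sl] = W * (1.0 - _smoothstep(u))
    # Right COP holds mid-foot, then rolls to the toes over the last 40%
    # of this double stance as the body passes over the foot.
    copR[sl] = np.where(
        u < 0.6, 0.55 * L, 0.55 * L + (0.12 * L - 0.55 * L) * (u - 0.6) / 0.4
    )

    # --- walking foot contacts -------------------------------------------
    def fill_contact(
        grf: np.ndarray,
        cop: np.ndarray,
        land: float,
        nominal_dur: float,
        until: float,
        scale: float,
    ) -> None:
        i0, i1 = I(land), min(I(until), n)
        if i1 <= i0:
            return
        s = (idx[i0:i1] / fs - land) / nominal_dur
        grf[i0:i1] = _stance_grf(s, W, scale)
        cop[i0:i1] = _stance_cop(s, L)

    stance_dur_L = dsd + ssL + dsd
    stance_dur_R = dsd + ssR + dsd
    # Left: lands at the first double stance, then at every R-L double
    # stance; the final landing persists into termination.
    fill_contact(grfL, copL, sw_end, stance_dur_L, walk_start + ssL + dsd, amp_l)
    for k in range(1, p.n_strides):
        land = stride_start(k) - dsd
        fill_contact(grfL, copL, land, stance_dur_L, land + stance_dur_L, amp_l)
    fill_contact(grfL, copL, walk_end - dsd, stance_dur_L, walk_end, amp_l)
    # Right: lands at every L-R double stance.
    for k in range(p.n_strides - 1):
        land = stride_start(k) + ssL
        fill_contact(grfR, copR, land, stance_dur_R, land + stance_dur_R, amp_r)
    fill_contact(grfR, copR, stride_start(p.n_strides - 1) + ssL, stance_dur_R, walk_end, amp_r)

    # --- termination: settle both feet to half body weight, COP mid -----
    blend = 0.3
    iwe = I(walk_end)
    if iwe < n:
        u = _smoothstep((t[iwe:] - walk_end) / blend)
        for grf, cop in ((grfL, copL), (grfR, copR)):
            g0 = grf[iwe - 1] if iwe > 0 else 0.5 * W
            c0 = cop[iwe - 1] if iwe > 0 and np.isfinite(cop[iwe - 1]) else 0.5 * L
            grf[iwe:] = 0.5 * W + (g0 - 0.5 * W) * (1.0 - u)
            cop[iwe:] = 0.5 * L + (c0 - 0.5 * L) * (1.0 - u)

    # --- flexion sum (anchor curve) --------------------------------------
    anchors: list[tuple[int, float]] = [
        (0, _SUMANG_BASE),
        (I(q1_end), _SUMANG_BASE),
        (I((ws_end + sw_end) / 2.0), _SUMANG_MAX),
        (I((sw_end + walk_start) / 2.0), _SUMANG_MIN),
    ]
    for k in range(p.n_strides):
        s0 = stride_start(k)
        anchors += [
            (I(s0 + ssL / 2.0), _SUMANG_MAX),
            (I(s0 + ssL + dsd / 2.0), _SUMANG_MIN),
            (I(s0 + ssL + dsd + ssR / 2.0), _SUMANG_MAX),
            (I(s0 + stride - dsd / 2.0), _SUMANG_MIN),
        ]
    anchors += [
        (iwe, 8.0),
        (I(walk_end + 0.3), _SUMANG_BASE),
        (n, _SUMANG_BASE),
    ]
    sum_ang = np.zeros(n)
    _fill_anchor_curve(sum_ang, anchors)

    # --- swing-phase gyro -------------------------------------------------
    def fill_swing(gyro: np.ndarray, t0: float, t1: float, amp: float) -> None:
        i0, i1 = I(t0), min(I(t1), n)
        if i1 <= i0:
            return
        u = (idx[i0:i1] / fs - t0) / (t1 - t0)
        gyro[i0:i1] = amp * np.sin(2.0 * np.pi * u)

    fill_swing(gyroL, ws_end, sw_end, _GYRO_AMP * amp_l)
    for k in range(p.n_strides):
        s0 = stride_start(k)
        fill_swing(gyroR, s0, s0 + ssL, _GYRO_AMP * amp_r)  # right swing
        fill_swing(gyroL, s0 + ssL + dsd, s0 + ssL + dsd + ssR, _GYRO_AMP * amp_l)

    # --- noise, clipping, COP sentinel mask ------------------------------
    rng = np.random.default_rng(p.seed)
    if p.sigma_grf > 0:
        grfL = grfL + rng.normal(0.0, p.sigma_grf, n)
        grfR = grfR + rng.normal(0.0, p.sigma_grf, n)
    grfL = np.clip(grfL, 0.0, None)
    grfR = np.clip(grfR, 0.0, None)
    if p.sigma_cop > 0:
        copL = copL + rng.normal(0.0, p.sigma_cop, n)
        copR = copR + rng.normal(0.0, p.sigma_cop, n)
    joints = {}
    for name, share in _JOINT_SHARES.items():
        ang = share * sum_ang
        if p.sigma_ang > 0:
            ang = ang + rng.normal(0.0, p.sigma_ang, n)
        joints[name] = ang
    if p.sigma_gyro > 0:
        gyroL = gyroL + rng.normal(0.0, p.sigma_gyro, n)
        gyroR = gyroR + rng.normal(0.0, p.sigma_gyro, n)
    copL[grfL < CONTACT_EPS_N] = np.nan
    copR[grfR < CONTACT_EPS_N] = np.nan

    meta = {
        "body_weight": W,
        "prosthetic_side": p.prosthetic_side,
        "seed": p.seed,
        "params": dataclasses.asdict(p),
        "init_start_idx": I(q1_end),
        "walk_start_idx": I(walk_start),
        "walk_end_idx": iwe,
        "term_end_idx": I(term_end),
    }
    return LabeledTrial(
        t=t,
        grfL=grfL,
        grfR=grfR,
        copyL=copL,
        copyR=copR,
        hipL=joints["hipL"],
        hipR=joints["hipR"],
        kneeL=joints["kneeL"],
        kneeR=joints["kneeR"],
        gyroL=gyroL,
        gyroR=gyroR,
        labels=labels,
        meta=meta,
    )


def make_snapshot(
    target_row: PhaseFlag, th: ThresholdSet, margin: float = 0.2
) -> tuple[SensorFrame, DerivedSignals]:
    """Construct a frame satisfying exactly the condition row of *target_row*.

    Every comparison in the target row is cleared by the given relative
    margin; signals not constrained by the row are set so that no
    higher-priority row fires, where that is logically possible (a single
    stance, for instance, always also satisfies the initiation row — the
    detector's priority order resolves that case).

    Raises
    ------
    ParameterError
        If the thresholds make the target row unsatisfiable at this
        margin (e.g. overlapping force bands).
    """
    if not 0.0 < margin < 1.0:
        raise ParameterError("margin must be in (0, 1)")

    def above(thr: float) -> float:
        # Clears "x > thr" by the relative margin (additive for thr <= 0).
        return thr * (1.0 + margin) if thr > 0 else thr + margin * max(abs(thr), 1.0)

    def below(thr: float) -> float:
        return thr * (1.0 - margin) if thr > 0 else thr - margin * max(abs(thr), 1.0)

    nan = float("nan")
    quiet_gyro = max(below(min(th.minG, th.termG)), 0.0)

    if target_row == PhaseFlag.QUIET_STANDING:
        grf = above(th.QSgrf)
        frame = _frame(
            grfL=grf, grfR=grf, copyL=above(th.midCOP), copyR=above(th.midCOP),
            sumAng=below(th.sumQS), gyroL=quiet_gyro, gyroR=quiet_gyro,
        )
        derived = DerivedSignals(
            grfDiff=max(below(th.init2), 0.0), sumAng=below(th.sumQS)
        )
    elif target_row == PhaseFlag.INITIATION:
        frame = _frame(
            grfL=max(below(th.QSgrf), 0.0), grfR=above(max(th.QSgrf, th.stanceR)),
            copyL=above(th.midCOP), copyR=above(th.midCOP),
            sumAng=above(th.sumAngInit), gyroL=0.0, gyroR=0.0,
        )
        derived = DerivedSignals(grfDiff=above(th.init1), sumAng=above(th.sumAngInit))
    elif target_row == PhaseFlag.TERMINATION:
        grf = above(th.QSgrf)
        gy = max(below(th.termG), 0.0)
        frame = _frame(
            grfL=grf, grfR=grf, copyL=above(th.midCOP), copyR=above(th.midCOP),
            sumAng=below(th.sumAngTerm), gyroL=gy, gyroR=gy,
        )
        derived = DerivedSignals(
            grfDiff=max(below(th.init1), 0.0), sumAng=below(th.sumAngTerm)
        )
    elif target_row == PhaseFlag.LEFT_STANCE:
        frame = _frame(
            grfL=above(max(th.stanceL, th.QSgrf)), grfR=max(below(th.stanceR), 0.0),
            copyL=above(th.midCOP), copyR=nan,
            sumAng=above(th.sumAngInit), gyroL=0.0, gyroR=_GYRO_AMP,
        )
        derived = DerivedSignals(grfDiff=above(th.init1), sumAng=above(th.sumAngInit))
    elif target_row == PhaseFlag.RIGHT_STANCE:
        frame = _frame(
            grfL=max(below(th.stanceL), 0.0), grfR=above(max(th.stanceR, th.QSgrf)),
            copyL=nan, copyR=above(th.midCOP),
            sumAng=above(th.sumAngInit), gyroL=_GYRO_AMP, gyroR=0.0,
        )
        derived = DerivedSignals(grfDiff=above(th.init1), sumAng=above(th.sumAngInit))
    elif target_row in (PhaseFlag.LR_DOUBLE, PhaseFlag.RL_DOUBLE):
        grf = above(max(th.stanceL, th.stanceR, th.QSgrf))
        toe_cop = below(th.midCOP)  # clears "< midCOP" by the margin
        heel_cop = above(th.midCOP)  # clears "> toeCOP", blocks the mirror row
        if target_row == PhaseFlag.LR_DOUBLE:
            copyL, copyR = toe_cop, heel_cop
        else:
            copyL, copyR = heel_cop, toe_cop
        sum_ang = above(max(th.minAng, th.sumAngTerm))
        frame = _frame(
            grfL=grf, grfR=grf, copyL=copyL, copyR=copyR,
            sumAng=sum_ang, gyroL=0.0, gyroR=0.0,
        )
        derived = DerivedSignals(
            grfDiff=max(below(th.init1), 0.0), sumAng=sum_ang
        )
    else:
        raise ParameterError(f"{target_row!r} is not a detectable condition row")

    if target_row not in eval_rows(frame, derived, th):
        raise ParameterError(
            f"thresholds make the {target_row.name} row unsatisfiable at "
            f"margin {margin}"
        )
    return frame, derived


def _frame(
    *,
    grfL: float,
    grfR: float,
    copyL: float,
    copyR: float,
    sumAng: float,
    gyroL: float,
    gyroR: float,
) -> SensorFrame:
    return SensorFrame(
        t=0.0,
        grfL=grfL,
        grfR=grfR,
        copyL=copyL,
        copyR=copyR,
        hipL=0.2 * sumAng,
        hipR=0.2 * sumAng,
        kneeL=0.3 * sumAng,
        kneeR=0.3 * sumAng,
        gyroL=gyroL,
        gyroR=gyroR,
    )
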