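"""Synthetic cohort generator for a perturbation-based balance training
(PBT) protocol on an instrumented walkway.

The generator emulates a two-group randomized study: older adults assigned
to an experimental group (EG) that receives pelvic force-pulse
perturbations from a walker-mounted cable trainer during overground
walking, or a control group (CG) that walks the same protocol without
training perturbations.  Each subject completes five walking trials —
GaitBaseline, TestPre, Training, TestPost, GaitPost — of 5 minutes each
except Training (10 minutes).  Test trials deliver randomized lateral
pulses (left or right); the EG's Training trial delivers diagonal pulses
(lateral combined with an up/down vertical component); the CG trains
unperturbed.  Pulses are square waves: 0 N between pulses, a high value of
~10% body weight for 100 ms, with random inter-pulse timing.

Three layers of output:

* footfall-level recordings — per-footfall COP/pressure time series with
  alternating feet on back-and-forth walkway passes, from which the
  analysis pipeline recomputes every gait metric;
* clinical score tables — instruments with fixed ranges (e.g. Berg
  Balance Scale 0-56, FES-I 16-64), two sessions per subject;
* a ground-truth log of every generating parameter and injected effect,
  for parameter-recovery and power tests.

A separate summary-level generator (:func:`simulate_summary_pair`) draws
per-subject per-condition metric summaries directly from the generative
distributions; it is the natural scale for calibration and power studies
of the statistical procedure, which consumes subject-level summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spatiotemporal import FootfallRecord

logger = logging.getLogger(__name__)

G_M_PER_S2 = 9.81

TRIAL_LABELS = ("GaitBaseline", "TestPre", "Training", "TestPost", "GaitPost")
GROUPS = ("EG", "CG")
LATERAL_DIRECTIONS = ("left", "right")
DIAGONAL_DIRECTIONS = ("left-up", "left-down", "right-up", "right-down")
ALL_DIRECTIONS = LATERAL_DIRECTIONS + DIAGONAL_DIRECTIONS

GAIT_METRICS = (
    "stride_length",
    "stride_velocity",
    "single_support_time",
    "integrated_pressure",
    "cisp_ap_pct",
    "cisp_ml_pct",
    "ss_cop_efficiency",
)

# walkway geometry and sampling
WALKWAY_LENGTH_CM = 488.0   # usable pressure-sensitive length
WALKWAY_MARGIN_CM = 20.0
FOOT_LENGTH_CM = 24.0
TURN_TIME_S = 2.0
MEANDER_CYCLES = 3          # ML meander periods per foot contact
PERTURB_GAIN_CM_PER_N = 0.01
PERTURB_TAU_S = 0.3


@dataclass(frozen=True)
class SubjectParams:
    """Generating parameters for one synthetic subject."""

    subject_id: str
    group: str                      # 'EG' or 'CG'
    body_weight: float              # kg
    mean_stride_length: float       # cm
    stride_length_sd: float         # cm
    mean_stride_velocity: float     # cm/s
    single_support_mean: float      # s, total per stride (both feet's phases)
    step_width: float               # cm
    cop_waviness: float             # cm, ML meander amplitude of the COP
    perturbation_susceptibility: float  # dimensionless

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if self.body_weight <= 0 or self.mean_stride_length <= 0 \
                or self.mean_stride_velocity <= 0:
            raise ValidationError("body weight, stride length and velocity "
                                  "must be positive")
        if self.stride_length_sd < 0 or self.cop_waviness < 0 \
                or self.perturbation_susceptibility < 0:
            raise ValidationError("sd/waviness/susceptibility must be >= 0")


@dataclass(frozen=True)
class PerturbationEvent:
    """One square force pulse applied to the pelvis."""

    onset_time: float  # s from trial start
    width: float       # s
    magnitude: float   # N (the square wave's high value; low value is 0 N)
    direction: str

    def __post_init__(self) -> None:
        if self.onset_time < 0 or self.width <= 0 or self.magnitude <= 0:
            raise ValidationError("bad perturbation event parameters")
        if self.direction not in ALL_DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")

    @property
    def ml_sign(self) -> float:
        """Lateral sign: + toward subject's right."""
        return -1.0 if self.direction.startswith("left") else 1.0

    @property
    def vertical_sign(self) -> float:
        """+1 down (loading), -1 up (unloading), 0 purely lateral."""
        if self.direction.endswith("-up"):
            return -1.0
        if self.direction.endswith("-down"):
            return 1.0
        return 0.0


@dataclass(frozen=True)
class ProtocolConfig:
    """Five-trial protocol parameters.

    Durations are in minutes; Training is the intervention trial and must
    be the longest.  ``force_fraction_bw`` is the pulse magnitude as a
    fraction of body weight.
    """

    trial_labels: tuple[str, ...] = TRIAL_LABELS
    trial_durations_min: dict[str, float] = field(default_factory=lambda: {
        "GaitBaseline": 5.0, "TestPre": 5.0, "Training": 10.0,
        "TestPost": 5.0, "GaitPost": 5.0,
    })
    force_fraction_bw: float = 0.10
    pulse_width: float = 0.100     # s
    min_gap: float = 3.0           # s, inter-onset gap lower bound
    max_gap: float = 8.0           # s, inter-onset gap upper bound
    rng_seed: int = 0
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if tuple(self.trial_labels) != TRIAL_LABELS:
            raise ValidationError(
                f"protocol requires the 5 trial labels {TRIAL_LABELS}")
        if set(self.trial_durations_min) != set(TRIAL_LABELS):
            raise ValidationError("trial_durations_min must cover all 5 trials")
        training = self.trial_durations_min["Training"]
        others = [v for k, v in self.trial_durations_min.items()
                  if k != "Training"]
        if not all(training > v for v in others):
            raise ValidationError("Training must be the longest trial")
        if not 0 < self.force_fraction_bw < 1:
            raise ValidationError("force_fraction_bw must be in (0, 1)")
        if not 0 < self.min_gap < self.max_gap:
            raise ValidationError("need 0 < min_gap < max_gap")
        if self.pulse_width <= 0:
            raise ValidationError("pulse_width must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """A group/session effect injected into the generator.

    ``effect_size`` is Cohen's d on the subject-summary scale of
    ``target_metric`` (standardized by the metric's between-subject SD).
    ``applies_to`` names the trial (or the later trial of a pair) the
    shift applies to; group_main effects shift the EG in every trial.
    """

    target_metric: str
    effect_type: str          # 'group_main' | 'session_main' | 'interaction'
    effect_size: float
    applies_to: str = "TestPost"

    def __post_init__(self) -> None:
        if self.effect_type not in ("group_main", "session_main", "interaction"):
            raise ValidationError(f"unknown effect_type {self.effect_type!r}")
        if not math.isfinite(self.effect_size):
            raise ValidationError("effect_size must be finite")
        known = set(GAIT_METRICS) | set(INSTRUMENT_RANGES)
        if self.target_metric not in known:
            raise ValidationError(f"unknown target_metric {self.target_metric!r}")


@dataclass
class TrialRecording:
    """One subject-trial: footfalls plus the generating ground truth."""

    subject_id: str
    group: str
    trial_label: str
    footfalls: list[FootfallRecord]
    schedule: list[PerturbationEvent]
    ground_truth: dict[str, float]


@dataclass
class CohortDataset:
    subjects: list[SubjectParams]
    recordings: list[TrialRecording]
    clinical: pd.DataFrame
    ground_truth: dict[str, dict[str, float]]  # "subject/trial" -> params


# ---------------------------------------------------------------------------
# cohort distributions (subject-level)
# ---------------------------------------------------------------------------
# Means/SDs chosen to emulate a healthy older-adult cohort walking at a
# self-selected pace: body weight ~71 kg, stride ~110 cm at ~100 cm/s,
# total single support ~0.78 s per stride, and a COP meander amplitude
# that yields single-stance efficiencies in the high-90s percent range.
COHORT_DISTRIBUTIONS = {
    "body_weight": (71.5, 17.0, 40.0, 130.0),
    "mean_stride_length": (110.0, 10.0, 60.0, 160.0),
    "stride_length_sd": (5.5, 1.5, 1.0, 12.0),
    "mean_stride_velocity": (100.0, 12.0, 55.0, 160.0),
    "single_support_mean": (0.78, 0.05, 0.55, 0.95),
    "step_width": (9.0, 1.5, 4.0, 16.0),
    "cop_waviness": (0.25, 0.08, 0.0, 1.0),
    "perturbation_susceptibility": (1.0, 0.2, 0.0, 3.0),
}

# summary-scale generative models: metric -> (mean, between-subject SD,
# within-subject (trial-to-trial) SD of the per-trial subject summary)
SUMMARY_MODELS = {
    "ss_cop_efficiency": (99.0, 0.6, 0.5),
    "stride_length": (110.0, 10.0, 3.0),
    "stride_velocity": (100.0, 12.0, 4.0),
    "single_support_time": (0.78, 0.05, 0.02),
    "integrated_pressure": (32.0, 8.0, 2.0),
    "cisp_ap_pct": (50.0, 5.0, 3.0),
    "cisp_ml_pct": (0.0, 3.0, 2.0),
}

# clinical instruments: name -> (low, high, mean, sd, day2 shift, integer)
INSTRUMENT_RANGES = {
    "BBS": (0.0, 56.0, 48.0, 3.0, 1.0, True),
    "SPPB": (0.0, 12.0, 11.9, 0.3, 0.0, True),
    "FES_I": (16.0, 64.0, 37.5, 9.5, -2.0, True),
    "FourStage_FeetSideBySide": (0.0, 10.0, 10.0, 0.2, 0.0, False),
    "FourStage_SemiTandem": (0.0, 10.0, 9.85, 0.5, 0.0, False),
    "FourStage_Tandem": (0.0, 10.0, 8.65, 1.9, 0.0, False),
    "FourStage_OneFootStand": (0.0, 10.0, 4.95, 2.8, 1.0, False),
    "MOCA": (0.0, 30.0, 28.0, 1.5, 0.0, True),
    "SDMT_60": (0.0, 110.0, 28.5, 9.0, 3.0, True),
    "SDMT_90": (0.0, 110.0, 44.0, 11.5, 4.0, True),
    "SDMT_C": (0.0, 600.0, 192.0, 48.0, -15.0, True),
    "TMT_A": (0.0, 300.0, 43.0, 21.0, -3.0, False),
    "TMT_B": (0.0, 400.0, 97.5, 44.0, -10.0, False),
}


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    """One draw from N(mean, sd) clipped to [lo, hi]."""
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def subject_stream(seed: int, subject_index: int, slot: int = 0) -> np.random.Generator:
    """Per-subject (and per-trial) RNG substream from one global seed.

    Spawn keys make every (subject, trial) stream independent of cohort
    size and trial order, so any subset regenerates identically.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject_index, slot))
    return np.random.default_rng(ss)


def draw_subject(subject_id: str, group: str, rng: np.random.Generator) -> SubjectParams:
    d = COHORT_DISTRIBUTIONS
    return SubjectParams(
        subject_id=subject_id,
        group=group,
        body_weight=_truncated_normal(rng, *d["body_weight"]),
        mean_stride_length=_truncated_normal(rng, *d["mean_stride_length"]),
        stride_length_sd=_truncated_normal(rng, *d["stride_length_sd"]),
        mean_stride_velocity=_truncated_normal(rng, *d["mean_stride_velocity"]),
        single_support_mean=_truncated_normal(rng, *d["single_support_mean"]),
        step_width=_truncated_normal(rng, *d["step_width"]),
        cop_waviness=_truncated_normal(rng, *d["cop_waviness"]),
        perturbation_susceptibility=_truncated_normal(
            rng, *d["perturbation_susceptibility"]),
    )


# ---------------------------------------------------------------------------
# perturbation schedules
# ---------------------------------------------------------------------------

def generate_perturbation_schedule(
    duration: float,
    config: ProtocolConfig,
    trial_label: str,
    group: str,
    rng: np.random.Generator,
    body_weight: float,
) -> list[PerturbationEvent]:
    """Random pulse schedule for one trial.

    Gait trials are unperturbed (no cables attached), as is the CG's
    Training trial.  Test trials restrict directions to lateral
    (left/right); the EG's Training trial uses diagonal directions.  All
    pulses share the configured width, magnitude = force fraction x body
    weight x g, and uniformly random inter-onset gaps in
    [min_gap, max_gap].
    """
    if duration <= 0:
        raise ValidationError(f"trial duration must be positive, got {duration}")
    if trial_label not in TRIAL_LABELS:
        raise ValidationError(f"unknown trial label {trial_label!r}")
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    if trial_label in ("GaitBaseline", "GaitPost"):
        return []
    if trial_label == "Training" and group == "CG":
        return []
    directions = (DIAGONAL_DIRECTIONS if trial_label == "Training"
                  else LATERAL_DIRECTIONS)
    magnitude = config.force_fraction_bw * body_weight * G_M_PER_S2
    events: list[PerturbationEvent] = []
    t = 0.0
    while True:
        t += rng.uniform(config.min_gap, config.max_gap)
        if t + config.pulse_width > duration:
            break
        events.append(PerturbationEvent(
            onset_time=t,
            width=config.pulse_width,
            magnitude=magnitude,
            direction=str(rng.choice(directions)),
        ))
    if not events:
        logger.warning("empty perturbation schedule for %s/%s (duration %.1f s, "
                       "gap bounds [%.1f, %.1f] s)", trial_label, group,
                       duration, config.min_gap, config.max_gap)
    return events


def force_waveform(schedule: Sequence[PerturbationEvent], t: np.ndarray) -> np.ndarray:
    """Scheduled lateral-plane force magnitude at times ``t`` (N).

    The square wave is exactly 0 N between pulses and exactly the pulse
    magnitude during [onset, onset + width).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for ev in schedule:
        out[(t >= ev.onset_time) & (t < ev.onset_time + ev.width)] = ev.magnitude
    return out


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _lateral_deflection(
    t: np.ndarray, schedule: Sequence[PerturbationEvent], susceptibility: float
) -> np.ndarray:
    """First-order lateral COP response to force pulses (cm).

    Each pulse adds an offset of gain x magnitude x susceptibility in the
    pulse's lateral direction at onset, decaying exponentially with time
    constant ``PERTURB_TAU_S``.  A deliberately simple, testable coupling.
    """
    dx = np.zeros_like(t)
    for ev in schedule:
        m = t >= ev.onset_time
        if not m.any():
            continue
        amp = PERTURB_GAIN_CM_PER_N * ev.magnitude * susceptibility * ev.ml_sign
        dx[m] += amp * np.exp(-(t[m] - ev.onset_time) / PERTURB_TAU_S)
    return dx


def _pressure_pulse_factor(
    t: np.ndarray, schedule: Sequence[PerturbationEvent],
    force_fraction: float, susceptibility: float,
) -> np.ndarray:
    """Pressure scaling from vertical pulse components (synthetic-only).

    An upward pulse unloads the walkway (factor < 1) and a downward pulse
    loads it, by the pulse's body-weight fraction, during the pulse
    window only.
    """
    f = np.ones_like(t)
    for ev in schedule:
        s = ev.vertical_sign
        if s == 0.0:
            continue
        m = (t >= ev.onset_time) & (t < ev.onset_time + ev.width)
        f[m] *= 1.0 + s * force_fraction * susceptibility
    return np.clip(f, 0.0, None)


def simulate_trial(
    subject: SubjectParams,
    trial_label: str,
    schedule: Sequence[PerturbationEvent],
    config: ProtocolConfig,
    rng: np.random.Generator,
    duration_s: float | None = None,
    param_shifts: dict[str, float] | None = None,
) -> TrialRecording:
    """Simulate one subject walking one trial on the walkway.

    Footfalls alternate L/R along back-and-forth passes; heel strikes
    follow the subject's stride-length/velocity distributions; the
    single-stance COP advances linearly from heel to toe with a sinusoidal
    mediolateral meander of amplitude ``cop_waviness`` (per-footfall
    amplitude jitter of 30%); pressure follows a half-sine arc scaled by
    body weight.  A force pulse overlapping a stance adds a decaying
    lateral COP deflection proportional to magnitude x susceptibility.

    ``param_shifts`` shifts generating parameters (used by effect
    injection); shifts are recorded in the ground truth.
    """
    if trial_label not in TRIAL_LABELS:
        raise ValidationError(f"unknown trial label {trial_label!r}")
    if duration_s is None:
        duration_s = config.trial_durations_min[trial_label] * 60.0
    if duration_s <= 0:
        raise ValidationError("trial duration must be positive")

    p = subject
    shifts = dict(param_shifts or {})
    mu_len = p.mean_stride_length + shifts.get("mean_stride_length", 0.0)
    sd_len = p.stride_length_sd
    mu_vel = p.mean_stride_velocity + shifts.get("mean_stride_velocity", 0.0)
    ss_total = p.single_support_mean + shifts.get("single_support_mean", 0.0)
    waviness = max(0.0, p.cop_waviness + shifts.get("cop_waviness", 0.0))
    mean_stride_t = mu_len / mu_vel
    if duration_s < 2.0 * mean_stride_t:
        raise ValidationError(
            f"duration {duration_s:.1f} s too short for one full stride")

    fs = config.sample_rate_hz
    usable = WALKWAY_LENGTH_CM - 2 * WALKWAY_MARGIN_CM
    vel_sd = 4.0  # cm/s, per-step speed jitter

    footfalls: list[FootfallRecord] = []
    t = 0.0
    pass_id = 0
    ff_counter = 0
    while True:
        direction = 1 if pass_id % 2 == 0 else -1
        y_pos = WALKWAY_MARGIN_CM if direction == 1 \
            else WALKWAY_LENGTH_CM - WALKWAY_MARGIN_CM
        dist = 0.0
        foot = "L"
        raw: list[tuple[float, float, float, str]] = []  # (hs_t, x, y, foot)
        while dist + mu_len / 2 < usable:
            # step length: sums of two consecutive steps have mean mu_len,
            # SD sd_len (per-step SD = sd_len / sqrt(2))
            step = max(10.0, rng.normal(mu_len / 2.0, sd_len / math.sqrt(2.0)))
            speed = max(20.0, rng.normal(mu_vel, vel_sd))
            if raw:
                t += step / speed
            lateral = p.step_width / 2.0 * (1 if foot == "R" else -1) * direction
            raw.append((t, lateral + rng.normal(0.0, 0.2), y_pos, foot))
            y_pos += direction * step
            dist += step
            foot = "R" if foot == "L" else "L"
            if t > duration_s:
                break
        if len(raw) >= 3:
            # contact duration: ends half a single-support phase before the
            # next ipsilateral heel strike
            for i, (hs, fx, fy, ft) in enumerate(raw):
                if i + 2 < len(raw):
                    c = (raw[i + 2][0] - hs) - ss_total / 2.0
                else:
                    c = 2.0 * mean_stride_t / 2.0 - ss_total / 2.0
                c = max(0.15, c + rng.normal(0.0, 0.01))
                n = max(3, int(round(c * fs)) + 1)
                tau = np.linspace(0.0, c, n)
                ts = hs + tau
                amp = max(0.0, waviness * (1.0 + 0.3 * rng.standard_normal()))
                x = fx + amp * np.sin(2.0 * np.pi * MEANDER_CYCLES * tau / c)
                y = fy + direction * FOOT_LENGTH_CM * tau / c
                pressure = p.body_weight * np.sin(np.pi * tau / c)
                pressure = np.clip(pressure, 0.0, None)
                if schedule:
                    x = x + _lateral_deflection(
                        ts, schedule, p.perturbation_susceptibility) * direction
                    pressure = pressure * _pressure_pulse_factor(
                        ts, schedule, config.force_fraction_bw,
                        p.perturbation_susceptibility)
                footfalls.append(FootfallRecord(
                    footfall_id=f"f{ff_counter:05d}",
                    subject_id=p.subject_id,
                    trial_label=trial_label,
                    pass_id=pass_id,
                    foot=ft,
                    t=ts, x=x, y=y, pressure=pressure,
                ))
                ff_counter += 1
        t += TURN_TIME_S
        pass_id += 1
        if t > duration_s:
            break

    ground_truth = {
        "mean_stride_length": mu_len,
        "stride_length_sd": sd_len,
        "mean_stride_velocity": mu_vel,
        "single_support_mean": ss_total,
        "cop_waviness": waviness,
        "body_weight": p.body_weight,
        "n_footfalls": float(len(footfalls)),
        "n_pulses": float(len(schedule)),
    }
    ground_truth.update({f"shift_{k}": v for k, v in shifts.items()})
    return TrialRecording(
        subject_id=p.subject_id, group=p.group, trial_label=trial_label,
        footfalls=footfalls, schedule=list(schedule), ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# effect injection
# ---------------------------------------------------------------------------

# mapping from a summary-scale Cohen's d to a generating-parameter shift
# (parameter name, shift per unit d).  Efficiency is shifted through the
# meander amplitude (monotone decreasing in efficiency), calibrated so
# that d = 1 lowers efficiency by roughly one between-subject SD.
_EFFECT_PARAM_MAP = {
    "stride_length": ("mean_stride_length", SUMMARY_MODELS["stride_length"][1]),
    "stride_velocity": ("mean_stride_velocity", SUMMARY_MODELS["stride_velocity"][1]),
    "single_support_time": ("single_support_mean",
                            SUMMARY_MODELS["single_support_time"][1]),
    "ss_cop_efficiency": ("cop_waviness", -0.08),
}


def _validate_effects(effects: Sequence[EffectSpec]) -> None:
    seen = set()
    for e in effects:
        key = (e.target_metric, e.effect_type)
        if key in seen:
            raise ValidationError(
                f"contradictory effects: duplicate {e.effect_type} on "
                f"{e.target_metric}")
        seen.add(key)


def _param_shifts_for(
    effects: Sequence[EffectSpec], group: str, trial_label: str
) -> dict[str, float]:
    shifts: dict[str, float] = {}
    for e in effects:
        if e.target_metric not in _EFFECT_PARAM_MAP:
            continue
        applies = (
            (e.effect_type == "group_main" and group == "EG")
            or (e.effect_type == "session_main" and trial_label == e.applies_to)
            or (e.effect_type == "interaction" and group == "EG"
                and trial_label == e.applies_to)
        )
        if applies:
            param, per_d = _EFFECT_PARAM_MAP[e.target_metric]
            shifts[param] = shifts.get(param, 0.0) + e.effect_size * per_d
    return shifts


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def assign_groups(n_per_group: int, rng: np.random.Generator) -> list[str]:
    """Balanced randomized group labels for 2 x n_per_group subjects."""
    labels = ["EG"] * n_per_group + ["CG"] * n_per_group
    rng.shuffle(labels)
    return labels


def simulate_cohort(
    n_per_group: int,
    config: ProtocolConfig | None = None,
    effects: Sequence[EffectSpec] = (),
    trial_durations_min: dict[str, float] | None = None,
) -> CohortDataset:
    """Simulate a balanced two-group cohort through the five-trial protocol.

    ``trial_durations_min`` overrides the protocol durations (useful for
    reduced-scale runs); the protocol defaults are the study conditions.
    Reproducibility comes from ``config.rng_seed`` via per-subject,
    per-trial substreams.
    """
    if n_per_group < 2:
        raise ValidationError("need n_per_group >= 2")
    config = config or ProtocolConfig()
    if trial_durations_min:
        merged = dict(config.trial_durations_min)
        merged.update(trial_durations_min)
        config = replace(config, trial_durations_min=merged)
    _validate_effects(effects)
    seed = config.rng_seed

    group_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2**20,)))
    labels = assign_groups(n_per_group, group_rng)

    subjects: list[SubjectParams] = []
    recordings: list[TrialRecording] = []
    ground_truth: dict[str, dict[str, float]] = {}
    for i, group in enumerate(labels):
        sid = f"s{i:03d}"
        subj = draw_subject(sid, group, subject_stream(seed, i, 0))
        subjects.append(subj)
        for j, label in enumerate(TRIAL_LABELS):
            trng = subject_stream(seed, i, j + 1)
            duration = config.trial_durations_min[label] * 60.0
            schedule = generate_perturbation_schedule(
                duration, config, label, group, trng, subj.body_weight)
            shifts = _param_shifts_for(effects, group, label)
            rec = simulate_trial(subj, label, schedule, config, trng,
                                 duration_s=duration, param_shifts=shifts)
            recordings.append(rec)
            ground_truth[f"{sid}/{label}"] = dict(rec.ground_truth)

    clinical = generate_clinical_scores(
        subjects, effects,
        np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                     spawn_key=(2**20 + 1,))))
    return CohortDataset(subjects=subjects, recordings=recordings,
                         clinical=clinical, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def generate_clinical_scores(
    subjects: Sequence[SubjectParams],
    effects: Sequence[EffectSpec],
    rng: np.random.Generator,
    noise_scale: float = 0.3,
    session_effects: bool = True,
    instruments: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Two-session clinical score table, clamped to each instrument's range.

    Each subject gets a latent baseline per instrument; the Day 2 score
    adds the instrument's typical session shift (suppressed when
    ``session_effects`` is false), test-retest noise of
    ``noise_scale`` x the instrument SD, and any injected effects.  Scores
    are clamped to the instrument's closed range after effect injection.
    With ``noise_scale = 0`` and ``session_effects = False`` the generator
    is degenerate: Day 1 equals Day 2 exactly.
    """
    names = list(instruments) if instruments is not None \
        else list(INSTRUMENT_RANGES)
    for name in names:
        if name not in INSTRUMENT_RANGES:
            raise ValidationError(f"unknown instrument {name!r}")
    _validate_effects(effects)
    rows = []
    for subj in subjects:
        for name in names:
            lo, hi, mean, sd, day2_shift, integer = INSTRUMENT_RANGES[name]
            base = rng.normal(mean, sd)
            for session in ("Day1", "Day2"):
                val = base + rng.normal(0.0, noise_scale * sd)
                if session == "Day2":
                    if session_effects:
                        val += day2_shift
                    for e in effects:
                        if e.target_metric != name:
                            continue
                        shift = e.effect_size * sd
                        if e.effect_type == "session_main":
                            val += shift
                        elif e.effect_type == "interaction" and subj.group == "EG":
                            val += shift
                for e in effects:
                    if (e.target_metric == name
                            and e.effect_type == "group_main"
                            and subj.group == "EG"):
                        val += e.effect_size * sd
                val = float(np.clip(val, lo, hi))
                if integer:
                    val = float(round(val))
                    val = float(np.clip(val, lo, hi))
                rows.append((subj.subject_id, subj.group, session, name, val))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "session", "instrument", "score"])


# ---------------------------------------------------------------------------
# summary-level generator (analysis scale)
# ---------------------------------------------------------------------------

def simulate_summary_pair(
    n_per_group: int,
    metric: str,
    conditions: tuple[str, str] = ("TestPre", "TestPost"),
    effects: Sequence[EffectSpec] = (),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-subject metric summaries for a two-condition, two-group design.

    Draws subject means from the metric's between-subject distribution
    and adds independent within-subject (trial-to-trial) noise per
    condition.  Effect sizes are exact on this scale: an interaction of
    size d shifts the EG's second condition by d x between-subject SD.
    This is the generator used for type-I and power studies of the
    statistical procedure, which operates on subject-level summaries.
    """
    if n_per_group < 2:
        raise ValidationError("need n_per_group >= 2")
    if metric not in SUMMARY_MODELS:
        raise ValidationError(f"no summary model for metric {metric!r}")
    _validate_effects(effects)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mean, sd_b, sd_w = SUMMARY_MODELS[metric]
    rows = []
    i = 0
    for group in ("EG", "CG"):
        for _ in range(n_per_group):
            sid = f"s{i:03d}"
            subj_mean = rng.normal(mean, sd_b)
            for ci, cond in enumerate(conditions):
                val = subj_mean + rng.normal(0.0, sd_w)
                for e in effects:
                    if e.target_metric != metric:
                        continue
                    shift = e.effect_size * sd_b
                    if e.effect_type == "group_main" and group == "EG":
                        val += shift
                    elif e.effect_type == "session_main" and ci == 1:
                        val += shift
                    elif (e.effect_type == "interaction" and group == "EG"
                          and ci == 1):
                        val += shift
                rows.append((sid, group, cond, val))
            i += 1
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition",
                                       "value"])
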