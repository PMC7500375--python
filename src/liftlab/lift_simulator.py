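"""Synthetic fingertip-force traces and weight reports.

The generative model produces, per trial, two-sensor three-axis force time
series sampled at ``fs`` and one raw weight report, with the statistical
structure the downstream analysis assumes:

* load force rises through one bell-shaped (minimum-jerk) rate pulse whose
  peak scales with the *expected* weight -- a convex combination of the
  previous and the actual object weight (sensorimotor memory);
* when the planned pulse cannot lift the object (light expected, heavy
  actual) a faster, larger corrective pulse follows, so the load-force rate
  shows two peaks;
* when the plan overshoots (heavy expected, light actual) liftoff occurs
  early and the load settles onto the actual-weight plateau shortly after;
* grip force leads load force, tracks it with a coupling ratio plus a
  safety margin, and carries a transient squeeze under dynamic stimulation;
* raw reports decrease with the previous object's weight and carry a
  participant-specific affine scale.

Everything is driven by :class:`numpy.random.Generator` state, so cohorts
are exactly reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session_design import (
    ObjectKind,
    OrderPair,
    SessionDesign,
    TmsCondition,
    TrialSpec,
    generate_session,
)

GROUPS = ("aIPS", "LO")

# minimum-jerk velocity bell: peak 1.875 at tau = 0.5, unit area
_BELL_PEAK = 1.875


def _bell(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 30.0 * tau**2 * (1.0 - tau) ** 2


def _bell_cum(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau * tau * (3.0 - 2.0 * tau)


@dataclass(frozen=True)
class TmsEffects:
    """Additive stimulation effects injected by the simulator."""

    d_pGFR_dynamic: float = 0.0  # N/s extra grip-rate peak, dynamic TMS, both groups
    d_pLFR_dynamic_LO_heavy: float = 0.0  # N/s extra late load-rate pulse, LO/dynamic/heavy
    d_percept_static_heavy: float = 0.0  # report-scale shift, static TMS on heavy


@dataclass(frozen=True)
class SimParams:
    """Physical and statistical parameters of the trial generator."""

    fs: float = 1000.0
    gravity: float = 9.81
    cube_masses: dict[str, float] = field(
        default_factory=lambda: {
            "light": 105.0,
            "heavy": 525.0,
            "medium": 317.0,
            "practice": 260.0,
        }
    )
    manipulandum_mass: float = 120.0  # grams
    memory_weight: float = 1.0  # fraction of expected weight from previous object
    lfr_gain: float = 8.0  # planned peak LFR (N/s) per newton of expected weight
    gf_lf_ratio: float = 1.4
    safety_margin: float = 1.0  # N of grip force beyond the coupled level
    correction_gain: float = 1.3  # target loading area as multiple of actual weight
    load_duration: float = 0.30  # s, planned loading pulse
    correction_duration: float = 0.18  # s, corrective pulse (faster than planned)
    correction_delay: float = 0.08  # s between planned pulse end and correction
    grip_lead: float = 0.05  # s grip onset precedes load onset
    grip_ramp: float = 0.12  # s rise time of the safety-margin preload
    reach_delay: float = 0.35  # s from screen-transparent to grip onset
    clamp_delay: float = 0.06  # s after liftoff before load settles to weight
    blend_duration: float = 0.15  # s settle time onto the weight plateau
    hold_duration: float = 1.0  # s of static hold retained after loading ends
    tms_effects: TmsEffects = field(default_factory=TmsEffects)
    noise_sd_force: float = 0.0  # N per channel
    noise_sd_report: float = 0.0  # report units (pre-scale)
    percept_prev_bias: float = 0.035  # report decrement per newton of previous weight
    participant_scale: float = 1.0
    participant_offset: float = 0.0
    artifact_probs: dict[str, float] = field(
        default_factory=lambda: {"p_drop": 0.0, "p_multilift": 0.0, "p_tms_fail": 0.0}
    )

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.cube_masses.values()) or self.manipulandum_mass < 0:
            raise ValueError("masses must be non-negative")
        if not 0.0 <= self.memory_weight <= 1.0:
            raise ValueError("memory_weight must be in [0, 1]")
        for k, p in self.artifact_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"artifact probability {k}={p} outside [0, 1]")
        if min(self.lfr_gain, self.gf_lf_ratio, self.safety_margin) < 0:
            raise ValueError("gains must be non-negative")

    def object_weight(self, obj: ObjectKind | str) -> float:
        """Total object weight in newtons: (cube + manipulandum) x gravity."""
        obj = ObjectKind(obj)
        try:
            cube = self.cube_masses[obj.value]
        except KeyError:
            raise ValueError(f"object {obj.value!r} has no defined mass") from None
        return (cube + self.manipulandum_mass) / 1000.0 * self.gravity


@dataclass
class ForceTrace:
    """Two-sensor, three-axis force samples for one trial.

    Axis convention per sensor: ``x`` is the horizontal grip-normal axis,
    ``z`` the vertical load axis, ``y`` a spare axis.
    """

    fs: float
    t: np.ndarray
    fxA: np.ndarray
    fyA: np.ndarray
    fzA: np.ndarray
    fxB: np.ndarray
    fyB: np.ndarray
    fzB: np.ndarray
    trial_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        chans = (self.fxA, self.fyA, self.fzA, self.fxB, self.fyB, self.fzB)
        if any(len(c) != n for c in chans):
            raise ValueError("all channels must share one length")
        if n < 2 * self.fs:
            raise ValueError("trace must span at least 2 s")
        if not all(np.all(np.isfinite(c)) for c in chans):
            raise ValueError("forces must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "fxA": self.fxA,
                "fyA": self.fyA,
                "fzA": self.fzA,
                "fxB": self.fxB,
                "fyB": self.fyB,
                "fzB": self.fzB,
            }
        )


@dataclass
class PerceptRecord:
    """One raw weight report on the participant's self-chosen scale."""

    raw_estimate: float
    z_estimate: float | None = None  # filled by the perception pipeline

    def __post_init__(self) -> None:
        if self.raw_estimate <= 0:
            raise ValueError("raw_estimate must be positive")


@dataclass
class TrialResult:
    spec: TrialSpec
    trace: ForceTrace | None
    percept: PerceptRecord
    artifact_flags: dict[str, bool]
    truth: dict[str, float]


def simulate_trial(
    spec: TrialSpec,
    prev_object: ObjectKind | str | None,
    params: SimParams,
    rng: np.random.Generator,
    participant: int = 0,
    group: str = "aIPS",
) -> TrialResult:
    """Simulate one grasp-lift-hold trial.

    Returns the force trace, the raw weight report and artifact flags,
    together with ground-truth event times for validating the extraction
    stage.
    """
    w_act = params.object_weight(spec.object)
    if prev_object is None:
        w_prev = w_act
    else:
        w_prev = params.object_weight(prev_object)
    w_exp = params.memory_weight * w_prev + (1.0 - params.memory_weight) * w_act

    fs = params.fs
    t_gf_on = params.reach_delay
    t_lf_on = t_gf_on + params.grip_lead

    # planned loading pulse: peak rate proportional to expected weight
    peak1_planned = params.lfr_gain * max(w_exp, 1e-6)
    area1 = peak1_planned * params.load_duration / _BELL_PEAK
    pulses = [(t_lf_on, params.load_duration, area1)]  # (start, duration, area)

    corrected = area1 < 1.02 * w_act
    if corrected:
        # under-scaled: fast corrective pulse after the planned one ends
        t2 = t_lf_on + params.load_duration + params.correction_delay
        area2 = max(params.correction_gain * w_act - area1, 0.2 * w_act)
        pulses.append((t2, params.correction_duration, area2))

    dyn = spec.tms_condition is TmsCondition.DYNAMIC
    eff = params.tms_effects
    extra_lfr = (
        dyn
        and group == "LO"
        and spec.object is ObjectKind.HEAVY
        and eff.d_pLFR_dynamic_LO_heavy > 0
    )

    t_load_end = max(t0 + dur for t0, dur, _ in pulses)
    duration = max(2.0, t_load_end + params.blend_duration + params.hold_duration)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    def cum_load(pulse_list):
        lf = np.zeros(n)
        for t0, dur, area in pulse_list:
            lf += area * _bell_cum((t - t0) / dur)
        return lf

    if extra_lfr:
        # a late additional drive pulse centred just past the planned rate
        # peak: raises and delays the maximum load-force rate and leaves a
        # second local maximum in the rate trace; amplitude is chosen so the
        # combined peak sits near planned + d
        main_start, main_dur, _ = pulses[0]
        t_center = main_start + 0.5 * main_dur + 0.07
        extra_dur = 0.12
        tau_c = (t_center - main_start) / main_dur
        residual = peak1_planned * float(_bell(np.asarray(tau_c))) / _BELL_PEAK
        p_extra = max(
            eff.d_pLFR_dynamic_LO_heavy,
            peak1_planned - residual + eff.d_pLFR_dynamic_LO_heavy,
        )
        pulses.append(
            (t_center - extra_dur / 2, extra_dur, p_extra * extra_dur / _BELL_PEAK)
        )

    lf_raw = cum_load(pulses)

    lift_idx = np.argmax(lf_raw >= w_act) if np.any(lf_raw >= w_act) else None
    if lift_idx is None:
        raise RuntimeError("simulated loading never reached object weight")
    t_lift = t[lift_idx]

    # after liftoff (+ a short mechanical delay) the load settles exactly
    # onto the weight plateau
    t_settle = t_lift + params.clamp_delay
    s = _smoothstep((t - t_settle) / params.blend_duration)
    lf = lf_raw * (1.0 - s) + w_act * s

    # grip: early safety-margin preload plus load-coupled component
    gf = params.safety_margin * _smoothstep(
        (t - t_gf_on) / params.grip_ramp
    ) + params.gf_lf_ratio * lf

    t_contact = t[np.argmax(gf > 0.4)] if np.any(gf > 0.4) else None
    if dyn and eff.d_pGFR_dynamic != 0.0 and t_contact is not None:
        # transient squeeze: returns to baseline, so static grip is untouched
        bump_dur = 0.3
        amp = eff.d_pGFR_dynamic * bump_dur / np.pi
        tau = np.clip((t - t_contact) / bump_dur, 0.0, 1.0)
        gf = gf + amp * np.sin(np.pi * tau) ** 2

    sd = params.noise_sd_force
    noise = rng.normal(0.0, sd, size=(6, n)) if sd > 0 else np.zeros((6, n))
    trace = ForceTrace(
        fs=fs,
        t=t,
        fxA=gf + noise[0],
        fyA=noise[1],
        fzA=lf / 2.0 + noise[2],
        fxB=gf + noise[3],
        fyB=noise[4],
        fzB=lf / 2.0 + noise[5],
        trial_meta={
            "participant": participant,
            "group": group,
            "trial_index": spec.index,
            "object": spec.object.value,
            "tms_condition": spec.tms_condition.value,
            "order_pair": spec.order_pair.value,
            "analyzable": spec.analyzable,
        },
    )

    # raw weight report: previous-weight bias, stimulation effect, affine
    # participant scale
    percept_drive = w_act - params.percept_prev_bias * w_prev
    if spec.tms_condition is TmsCondition.STATIC and spec.object is ObjectKind.HEAVY:
        percept_drive += eff.d_percept_static_heavy
    if params.noise_sd_report > 0:
        percept_drive += rng.normal(0.0, params.noise_sd_report)
    raw = params.participant_scale * max(percept_drive, 0.05) + params.participant_offset
    percept = PerceptRecord(raw_estimate=max(raw, 1e-3))

    probs = params.artifact_probs
    flags = {
        "dropped": bool(rng.random() < probs.get("p_drop", 0.0)),
        "multiple_lifts": bool(rng.random() < probs.get("p_multilift", 0.0)),
        "tms_failed": bool(
            spec.tms_condition is not TmsCondition.NONE
            and rng.random() < probs.get("p_tms_fail", 0.0)
        ),
        "not_lifted": False,
        "data_failure": False,
    }

    truth = {
        "t_gf_onset": t_gf_on,
        "t_lf_onset": t_lf_on,
        "t_liftoff": t_lift,
        "weight": w_act,
        "expected_weight": w_exp,
        "peak1_lfr_planned": peak1_planned,
        "n_load_pulses": 2 if corrected else 1,
    }
    return TrialResult(spec=spec, trace=trace, percept=percept,
                       artifact_flags=flags, truth=truth)


@dataclass
class ParticipantData:
    participant: int
    group: str
    seed: int
    design: SessionDesign
    trials: list[TrialResult]


@dataclass
class CohortData:
    params: SimParams
    seed: int
    participants: list[ParticipantData]


def _participant_params(
    base: SimParams, rng: np.random.Generator
) -> SimParams:
    scale = float(rng.uniform(0.6, 1.8))
    offset = float(rng.uniform(0.0, 0.5))
    return replace(base, participant_scale=scale, participant_offset=offset)


def simulate_participant(
    participant: int,
    group: str,
    seed_seq: np.random.SeedSequence,
    params: SimParams,
    n_reps_per_cell: int = 10,
    keep_traces: bool = True,
) -> ParticipantData:
    """Simulate one participant's full session."""
    design_seed = int(seed_seq.generate_state(1)[0])
    rng = np.random.default_rng(seed_seq)
    p_params = _participant_params(params, rng)
    design = generate_session(design_seed, n_reps_per_cell=n_reps_per_cell)
    trials: list[TrialResult] = []
    prev: ObjectKind | None = None
    for spec in design.trials:
        res = simulate_trial(spec, prev, p_params, rng,
                             participant=participant, group=group)
        if not keep_traces:
            res.trace = None
        trials.append(res)
        prev = spec.object
    return ParticipantData(
        participant=participant, group=group, seed=design_seed,
        design=design, trials=trials,
    )


def iter_cohort(
    n_per_group: int,
    params: SimParams,
    seed: int,
    n_reps_per_cell: int = 10,
    keep_traces: bool = True,
):
    """Yield :class:`ParticipantData` for groups aIPS and LO, lazily.

    Per-participant seeds are derived by spawning the master seed sequence,
    so streams are independent and the whole cohort is reproducible.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(2 * n_per_group)
    pid = 0
    for group in GROUPS:
        for _ in range(n_per_group):
            yield simulate_participant(
                pid, group, children[pid], params,
                n_reps_per_cell=n_reps_per_cell, keep_traces=keep_traces,
            )
            pid += 1


def simulate_cohort(
    n_per_group: int,
    params: SimParams,
    seed: int,
    n_reps_per_cell: int = 10,
    keep_traces: bool = True,
) -> CohortData:
    """Simulate a full two-group cohort (eager version of :func:`iter_cohort`)."""
    participants = list(
        iter_cohort(n_per_group, params, seed,
                    n_reps_per_cell=n_reps_per_cell, keep_traces=keep_traces)
    )
    return CohortData(params=params, seed=seed, participants=participants)


def simulate_cell_means(
    n_per_group: int,
    seed: int,
    effects: dict[str, float] | None = None,
    sigma: float = 1.0,
    dv: str = "value",
) -> pd.DataFrame:
    """Draw participant-level cell means directly, without force traces.

    This is the fast path for statistical calibration studies (type-I error,
    power): one value per participant x order pair x stimulation condition,
    ``value = sum(effect offsets) + N(0, sigma)``.  Supported effect keys:
    ``previous``, ``current``, ``condition_dynamic``, ``condition_static``,
    ``location`` -- each adds half its size for the 'high' level (heavy /
    dynamic-or-static / LO) and subtracts half for the other.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    pairs = ["LL", "HL", "LH", "HH"]
    conds = ["dynamic", "static", "none"]
    rows = []
    pid = 0
    for group in GROUPS:
        for _ in range(n_per_group):
            for pair in pairs:
                prev_heavy = pair[0] == "H"
                cur_heavy = pair[1] == "H"
                for cond in conds:
                    mu = 0.0
                    mu += effects.get("previous", 0.0) * (0.5 if prev_heavy else -0.5)
                    mu += effects.get("current", 0.0) * (0.5 if cur_heavy else -0.5)
                    if cond == "dynamic":
                        mu += effects.get("condition_dynamic", 0.0)
                    elif cond == "static":
                        mu += effects.get("condition_static", 0.0)
                    mu += effects.get("location", 0.0) * (0.5 if group == "LO" else -0.5)
                    rows.append(
                        {
                            "participant": pid,
                            "group": group,
                            "order_pair": pair,
                            "tms_condition": cond,
                            "dv": dv,
                            "value": mu + rng.normal(0.0, sigma),
                        }
                    )
            pid += 1
    return pd.DataFrame(rows)


def simulate_coupled_trials(
    n_participants: int,
    n_trials: int,
    slope: float,
    seed: int,
    noise_sd: float = 1.0,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Trial-level records with a linear percept~covariate coupling.

    Used for parameter-recovery and type-I studies of the mixed-model
    regression: ``percept = slope * covariate + AR(1) noise`` within each
    participant, with balanced current-weight / condition / location labels.
    """
    rng = np.random.default_rng(seed)
    rows = []
    conds = ["dynamic", "static", "none"]
    for pid in range(n_participants):
        group = GROUPS[pid % 2]
        cov = rng.normal(0.0, 1.0, n_trials)
        eps = np.empty(n_trials)
        eps[0] = rng.normal(0.0, noise_sd)
        for i in range(1, n_trials):
            eps[i] = rho * eps[i - 1] + rng.normal(
                0.0, noise_sd * np.sqrt(1.0 - rho**2)
            )
        percept = slope * cov + eps
        for i in range(n_trials):
            rows.append(
                {
                    "participant": pid,
                    "location": group,
                    "current": "heavy" if i % 2 else "light",
                    "tms_condition": conds[i % 3],
                    "order": i,
                    "covariate": cov[i],
                    "percept": percept[i],
                }
            )
    return pd.DataFrame(rows)
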