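"""Force-parameter extraction from grasp-and-lift traces.

Implements the analysis conventions: zero-phase second-order Butterworth
low-pass filtering at 15 Hz; grip force as the mean of the two sensors'
horizontal forces and load force as the sum of the verticals; 0.1 N force
onsets and a 0.4 N contact trigger; liftoff where load force overcomes
object weight; force rates as first time derivatives; peak and first-peak
rates in the window from grip onset to 50 ms after liftoff (the first peak
must reach at least 30% of the maximum); static grip force averaged 600-800
ms after liftoff; and the two-stage trial-exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .session_design import TmsCondition
from .lift_simulator import ForceTrace

LOWPASS_CUTOFF_HZ = 15.0
ONSET_THRESHOLD_N = 0.1
CONTACT_TRIGGER_N = 0.4
DEBOUNCE_S = 0.010
PEAK_WINDOW_AFTER_LIFTOFF_S = 0.050
FIRST_PEAK_MIN_FRACTION = 0.30
STATIC_WINDOW_S = (0.600, 0.800)
TMS_PULSE_INTERVAL_S = 0.100  # 3 pulses at 10 Hz
TMS_STATIC_DELAY_S = 0.500

#: flags excluding a trial from the perceptual analysis
PERCEPTUAL_EXCLUSION_FLAGS = ("tms_failed", "not_lifted")
#: additional flags excluding a trial from the force analysis
FORCE_EXCLUSION_FLAGS = ("multiple_lifts", "dropped", "data_failure")


@dataclass
class LiftEvents:
    """Detected event times (seconds from trial start)."""

    t_gf_onset: float | None
    t_lf_onset: float | None
    t_contact_trigger: float | None
    t_liftoff: float | None
    lifted: bool


@dataclass
class LiftMetrics:
    """Per-trial force parameters."""

    peak_LFR: float
    peak_GFR: float
    peak1_LFR: float
    peak1_GFR: float
    tp_LFR: float
    tp_GFR: float
    gf_static: float


def lowpass_filter(
    series: np.ndarray, fs: float, cutoff: float = LOWPASS_CUTOFF_HZ
) -> np.ndarray:
    """Zero-phase (forward-backward) second-order Butterworth low-pass.

    The bidirectional pass doubles the effective order but introduces no
    phase lag, so detected event times are unbiased.
    """
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    series = np.asarray(series, dtype=float)
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * 6  # filtfilt default for a single biquad, via sosfiltfilt
    if len(series) <= padlen:
        raise ValueError(f"series too short to filter (need > {padlen} samples)")
    return signal.sosfiltfilt(sos, series)


def compose_gf_lf(trace: ForceTrace) -> tuple[np.ndarray, np.ndarray]:
    """Grip force = mean |horizontal| of both sensors; load = sum of verticals."""
    gf = (np.abs(trace.fxA) + np.abs(trace.fxB)) / 2.0
    lf = trace.fzA + trace.fzB
    return gf, lf


def _sustained_crossing(
    series: np.ndarray, threshold: float, fs: float, debounce: float = DEBOUNCE_S
) -> int | None:
    """First index where `series > threshold` holds for >= debounce seconds."""
    above = series > threshold
    win = max(1, int(round(debounce * fs)))
    if len(above) < win:
        return None
    # rolling all-true via cumulative sum of the boolean series
    csum = np.concatenate([[0], np.cumsum(above)])
    ok = (csum[win:] - csum[:-win]) == win
    idx = np.flatnonzero(ok)
    return int(idx[0]) if idx.size else None


def detect_events(
    gf: np.ndarray, lf: np.ndarray, fs: float, object_weight: float
) -> LiftEvents:
    """Detect onsets, the contact trigger and liftoff on filtered series."""
    if object_weight <= 0:
        raise ValueError("object_weight must be positive")
    i_gf = _sustained_crossing(gf, ONSET_THRESHOLD_N, fs)
    i_lf = _sustained_crossing(lf, ONSET_THRESHOLD_N, fs)
    trig = np.flatnonzero(gf > CONTACT_TRIGGER_N)
    i_trig = int(trig[0]) if trig.size else None
    i_lift = _sustained_crossing(lf, object_weight, fs)
    return LiftEvents(
        t_gf_onset=None if i_gf is None else i_gf / fs,
        t_lf_onset=None if i_lf is None else i_lf / fs,
        t_contact_trigger=None if i_trig is None else i_trig / fs,
        t_liftoff=None if i_lift is None else i_lift / fs,
        lifted=i_lift is not None,
    )


def compute_rates(
    gf: np.ndarray, lf: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """First time derivatives (central differences, one-sided endpoints)."""
    if len(gf) < 3 or len(lf) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / fs
    return np.gradient(np.asarray(gf, float), dt), np.gradient(
        np.asarray(lf, float), dt
    )


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus contribute their first sample."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    # run-length compress equal neighbours, then strict comparison
    change = np.flatnonzero(np.diff(x) != 0.0)
    if change.size < 2:
        return np.array([], dtype=int)
    starts = np.concatenate([[0], change + 1])  # first index of each run
    vals = x[starts]
    inner = np.flatnonzero((vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])) + 1
    return starts[inner]


def _peaks_in_window(
    rate: np.ndarray, i0: int, i1: int
) -> tuple[float, float, int]:
    """(global peak, first qualifying peak, global peak index) in [i0, i1)."""
    w = rate[i0:i1]
    if w.size == 0:
        raise ValueError("empty peak-search window")
    i_peak = int(np.argmax(w))  # earliest index on ties
    peak = float(w[i_peak])
    cand = local_maxima(w)
    cand = cand[w[cand] >= FIRST_PEAK_MIN_FRACTION * peak]
    first = float(w[cand[0]]) if cand.size else peak
    return peak, first, i0 + i_peak


def extract_metrics(
    gf: np.ndarray,
    lf: np.ndarray,
    gfr: np.ndarray,
    lfr: np.ndarray,
    events: LiftEvents,
    fs: float,
) -> LiftMetrics:
    """Peak / first-peak force rates, times to peak, and static grip force.

    The search window runs from grip-force onset to 50 ms after liftoff
    (half-open).  Times to peak are measured from grip-force onset to the
    global rate peak.  Static grip force averages 600-800 ms after liftoff;
    the trace must extend that far.
    """
    if not events.lifted or events.t_liftoff is None or events.t_gf_onset is None:
        raise ValueError("extract_metrics requires a lifted trial with events")
    i0 = int(round(events.t_gf_onset * fs))
    i1 = int(round((events.t_liftoff + PEAK_WINDOW_AFTER_LIFTOFF_S) * fs)) + 1
    i1 = min(i1, len(lfr))

    peak_lfr, peak1_lfr, ip_lfr = _peaks_in_window(lfr, i0, i1)
    peak_gfr, peak1_gfr, ip_gfr = _peaks_in_window(gfr, i0, i1)

    ia = int(round((events.t_liftoff + STATIC_WINDOW_S[0]) * fs))
    ib = int(round((events.t_liftoff + STATIC_WINDOW_S[1]) * fs))
    if ib > len(gf):
        raise ValueError("trace ends before the static grip-force window")
    gf_static = float(np.mean(gf[ia:ib]))

    return LiftMetrics(
        peak_LFR=peak_lfr,
        peak_GFR=peak_gfr,
        peak1_LFR=peak1_lfr,
        peak1_GFR=peak1_gfr,
        tp_LFR=ip_lfr / fs - events.t_gf_onset,
        tp_GFR=ip_gfr / fs - events.t_gf_onset,
        gf_static=gf_static,
    )


def schedule_tms(
    events: LiftEvents, condition: TmsCondition | str
) -> list[float]:
    """Pulse times for a 3-pulse 10 Hz burst.

    Dynamic stimulation starts at the contact trigger; static stimulation
    starts 500 ms after liftoff; the no-stimulation condition is empty.
    """
    condition = TmsCondition(condition)
    offsets = [i * TMS_PULSE_INTERVAL_S for i in range(3)]
    if condition is TmsCondition.NONE:
        return []
    if condition is TmsCondition.DYNAMIC:
        if events.t_contact_trigger is None:
            raise ValueError("dynamic stimulation requires a contact trigger")
        return [events.t_contact_trigger + o for o in offsets]
    if events.t_liftoff is None:
        raise ValueError("static stimulation requires a liftoff")
    return [events.t_liftoff + TMS_STATIC_DELAY_S + o for o in offsets]


def metrics_from_trace(
    trace: ForceTrace, object_weight: float
) -> tuple[LiftEvents, LiftMetrics | None]:
    """Filter, compose, detect and extract in one call.

    Returns ``(events, None)`` when the object was never lifted.
    """
    gf_raw, lf_raw = compose_gf_lf(trace)
    gf = lowpass_filter(gf_raw, trace.fs)
    lf = lowpass_filter(lf_raw, trace.fs)
    events = detect_events(gf, lf, trace.fs, object_weight)
    if not events.lifted:
        return events, None
    gfr, lfr = compute_rates(gf, lf, trace.fs)
    return events, extract_metrics(gf, lf, gfr, lfr, events, trace.fs)


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Boolean inclusion masks (perceptual, force) for a tidy trial table.

    The table needs an ``analyzable`` column and one boolean column per
    artifact flag.  The perceptual set drops failed-stimulation and
    not-lifted trials; the force set additionally drops multiple lifts,
    drops, and data failures.  Non-analyzable trials are excluded from both.
    """
    base = trials["analyzable"].astype(bool)
    percept = base.copy()
    for flag in PERCEPTUAL_EXCLUSION_FLAGS:
        if flag in trials:
            percept &= ~trials[flag].astype(bool)
    force = percept.copy()
    for flag in FORCE_EXCLUSION_FLAGS:
        if flag in trials:
            force &= ~trials[flag].astype(bool)
    return percept, force
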