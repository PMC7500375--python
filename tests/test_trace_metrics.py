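import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import brute_local_maxima, brute_peaks

from liftlab.lift_simulator import ForceTrace, SimParams, simulate_trial
from liftlab.session_design import ObjectKind, OrderPair, TmsCondition, TrialSpec
from liftlab.trace_metrics import (
    LiftEvents,
    apply_exclusions,
    compose_gf_lf,
    compute_rates,
    detect_events,
    extract_metrics,
    local_maxima,
    lowpass_filter,
    metrics_from_trace,
    schedule_tms,
)


def _trace(fxA, fzA, fxB=None, fzB=None, fs=100.0):
    n = len(fxA)
    z = np.zeros(n)
    return ForceTrace(
        fs=fs, t=np.arange(n) / fs,
        fxA=np.asarray(fxA, float), fyA=z,
        fzA=np.asarray(fzA, float),
        fxB=np.asarray(fxB if fxB is not None else fxA, float), fyB=z,
        fzB=np.asarray(fzB if fzB is not None else fzA, float),
    )


class TestLowpassFilter:
    def test_dc_preserved(self):
        out = lowpass_filter(np.full(1000, 3.7), fs=1000.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_impulse_gain(self):
        x = np.zeros(2000)
        x[1000] = 1.0
        out = lowpass_filter(x, fs=1000.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_50hz_attenuated_20db(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        out = lowpass_filter(x, fs=1000.0)
        mid = out[1000:3000]
        assert np.max(np.abs(mid)) < 0.1  # > 20 dB down

    def test_passband_preserved(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 2 * t)
        out = lowpass_filter(x, fs=1000.0)
        np.testing.assert_allclose(out[500:3500], x[500:3500], atol=0.01)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(5), fs=1000.0)

    def test_low_fs_raises(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(100), fs=20.0)


class TestComposeGfLf:
    def test_definition(self):
        n = 200
        tr = _trace(np.full(n, 2.0), np.full(n, 1.0),
                    fxB=np.full(n, 4.0), fzB=np.full(n, 1.0))
        gf, lf = compose_gf_lf(tr)
        np.testing.assert_allclose(gf, 3.0)
        np.testing.assert_allclose(lf, 2.0)

    def test_zero_trace(self):
        tr = _trace(np.zeros(200), np.zeros(200))
        gf, lf = compose_gf_lf(tr)
        assert not gf.any() and not lf.any()

    def test_symmetric_sensors(self):
        h = np.linspace(0, 5, 300)
        tr = _trace(h, np.zeros(300))
        gf, _ = compose_gf_lf(tr)
        np.testing.assert_allclose(gf, h)

    def test_absolute_value_of_horizontals(self):
        n = 200
        tr = _trace(np.full(n, -2.0), np.zeros(n), fxB=np.full(n, 2.0))
        gf, _ = compose_gf_lf(tr)
        np.testing.assert_allclose(gf, 2.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ForceTrace(
                fs=100.0, t=np.arange(300) / 100.0,
                fxA=np.zeros(300), fyA=np.zeros(300), fzA=np.zeros(300),
                fxB=np.zeros(299), fyB=np.zeros(300), fzB=np.zeros(300),
            )


class TestDetectEvents:
    def test_ramp_onsets(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        gf = 10 * t
        ev = detect_events(gf, 10 * t, fs, object_weight=2.2)
        assert ev.t_gf_onset == pytest.approx(0.010, abs=0.0015)
        assert ev.t_contact_trigger == pytest.approx(0.040, abs=0.0015)

    def test_ramp_liftoff(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        lf = 10 * t
        ev = detect_events(np.zeros_like(lf), lf, fs, object_weight=2.2)
        assert ev.lifted
        assert ev.t_liftoff == pytest.approx(0.220, abs=0.0015)

    def test_never_lifted(self):
        ev = detect_events(np.zeros(1000), np.zeros(1000), 1000.0, 2.2)
        assert not ev.lifted
        assert ev.t_liftoff is None

    def test_debounce_rejects_spike(self):
        fs = 1000.0
        lf = np.zeros(2000)
        lf[100:105] = 5.0  # 5 ms spike, below the 10 ms debounce
        lf[1000:] = 5.0
        ev = detect_events(np.zeros_like(lf), lf, fs, object_weight=2.2)
        assert ev.t_liftoff == pytest.approx(1.000, abs=0.0015)

    def test_invalid_weight_raises(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(100), np.zeros(100), 1000.0, 0.0)


class TestComputeRates:
    def test_linear_ramp(self):
        fs = 1000.0
        t = np.arange(1000) / fs
        gfr, lfr = compute_rates(5 * t, 5 * t, fs)
        np.testing.assert_allclose(gfr[1:-1], 5.0, atol=1e-9)

    def test_constant_zero_rate(self):
        gfr, _ = compute_rates(np.full(500, 2.0), np.full(500, 2.0), 1000.0)
        np.testing.assert_allclose(gfr, 0.0, atol=1e-12)

    def test_sinusoid_derivative(self):
        fs = 1000.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * t)
        gfr, _ = compute_rates(x, x, fs)
        np.testing.assert_allclose(gfr, 2 * np.pi * np.cos(2 * np.pi * t),
                                   atol=1e-3)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            compute_rates(np.ones(2), np.ones(2), 1000.0)


class TestLocalMaxima:
    def test_plateau_takes_first_sample(self):
        x = np.array([0, 5, 7, 7, 7, 3, 0], float)
        assert list(local_maxima(x)) == [2]

    def test_strict_interior_maxima(self):
        x = np.array([0, 4, 1, 10, 2], float)
        assert list(local_maxima(x)) == [1, 3]

    def test_monotone_has_none(self):
        assert len(local_maxima(np.arange(10.0))) == 0

    @given(st.lists(st.integers(-5, 5), min_size=3, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, vals):
        x = np.asarray(vals, float)
        assert list(local_maxima(x)) == brute_local_maxima(x)


def _bump(t, center, width, height):
    return height * np.exp(-0.5 * ((t - center) / width) ** 2)


class TestExtractMetrics:
    fs = 1000.0

    def _events(self, liftoff):
        return LiftEvents(
            t_gf_onset=0.0, t_lf_onset=0.0, t_contact_trigger=0.0,
            t_liftoff=liftoff, lifted=True,
        )

    def _series(self, heights, centers):
        t = np.arange(1200) / self.fs
        lfr = sum(_bump(t, c, 0.01, h) for h, c in zip(heights, centers))
        return t, np.asarray(lfr)

    def test_two_peak_selection(self):
        t, lfr = self._series([4, 10], [0.05, 0.15])
        gf = np.full_like(t, 5.0)
        m = extract_metrics(gf, gf, lfr, lfr, self._events(0.2), self.fs)
        assert m.peak_LFR == pytest.approx(10, abs=0.01)
        assert m.peak1_LFR == pytest.approx(4, abs=0.01)
        assert m.tp_LFR == pytest.approx(0.15, abs=0.002)

    def test_small_first_peak_skipped(self):
        t, lfr = self._series([2, 10], [0.05, 0.15])
        gf = np.full_like(t, 5.0)
        m = extract_metrics(gf, gf, lfr, lfr, self._events(0.2), self.fs)
        assert m.peak1_LFR == pytest.approx(10, abs=0.01)

    def test_constant_gf_static(self):
        t, lfr = self._series([10], [0.1])
        gf = np.full_like(t, 5.0)
        m = extract_metrics(gf, gf, lfr, lfr, self._events(0.2), self.fs)
        assert m.gf_static == pytest.approx(5.0)

    def test_first_peak_rule_invariants(self):
        t, lfr = self._series([4, 10], [0.05, 0.15])
        gf = np.full_like(t, 5.0)
        m = extract_metrics(gf, gf, lfr, lfr, self._events(0.2), self.fs)
        assert m.peak1_LFR <= m.peak_LFR
        assert m.peak1_LFR >= 0.3 * m.peak_LFR
        assert m.tp_LFR >= 0

    def test_short_trace_raises(self):
        t, lfr = self._series([10], [0.1])
        gf = np.full_like(t, 5.0)
        with pytest.raises(ValueError):
            extract_metrics(gf, gf, lfr, lfr, self._events(0.9), self.fs)

    def test_not_lifted_raises(self):
        ev = LiftEvents(0.0, 0.0, 0.0, None, lifted=False)
        x = np.zeros(1000)
        with pytest.raises(ValueError):
            extract_metrics(x, x, x, x, ev, self.fs)

    def test_oracle_equivalence_random_traces(self, rng):
        # peak/first-peak equal an exhaustive local-maximum scan
        fs = 1000.0
        for _ in range(200):
            n = int(rng.integers(1000, 1600))
            raw = rng.normal(0, 1, n).cumsum()
            rate = lowpass_filter(raw, fs) + 2.0
            liftoff = (n - 850) / fs
            gf = np.full(n, 1.0)
            ev = self._events(liftoff)
            m = extract_metrics(gf, gf, rate, rate, ev, fs)
            i0, i1 = 0, int(round((liftoff + 0.05) * fs)) + 1
            peak, first = brute_peaks(rate, i0, min(i1, n))
            assert m.peak_LFR == pytest.approx(peak, rel=1e-12)
            assert m.peak1_LFR == pytest.approx(first, rel=1e-12)


class TestScheduleTms:
    def test_dynamic(self):
        ev = LiftEvents(0.9, 0.95, 1.0, 1.5, True)
        assert schedule_tms(ev, "dynamic") == pytest.approx([1.0, 1.1, 1.2])

    def test_static(self):
        ev = LiftEvents(0.9, 0.95, 1.0, 2.0, True)
        assert schedule_tms(ev, "static") == pytest.approx([2.5, 2.6, 2.7])

    def test_none(self):
        ev = LiftEvents(None, None, None, None, False)
        assert schedule_tms(ev, "none") == []

    def test_missing_events_raise(self):
        ev = LiftEvents(0.9, 0.95, None, None, False)
        with pytest.raises(ValueError):
            schedule_tms(ev, "dynamic")
        with pytest.raises(ValueError):
            schedule_tms(ev, "static")

    def test_burst_span_200ms(self):
        ev = LiftEvents(0.0, 0.0, 0.42, 1.0, True)
        pulses = schedule_tms(ev, TmsCondition.DYNAMIC)
        assert (pulses[-1] - pulses[0]) == pytest.approx(0.200)


class TestApplyExclusions:
    def _table(self, n=120, **overrides):
        df = pd.DataFrame(
            {
                "analyzable": [True] * n,
                "tms_failed": [False] * n,
                "not_lifted": [False] * n,
                "multiple_lifts": [False] * n,
                "dropped": [False] * n,
                "data_failure": [False] * n,
            }
        )
        for col, idx in overrides.items():
            df.loc[idx, col] = True
        return df

    def test_clean_trials_all_included(self):
        p, f = apply_exclusions(self._table())
        assert p.sum() == 120 and f.sum() == 120

    def test_tms_failed_excluded_from_both(self):
        p, f = apply_exclusions(self._table(tms_failed=[3]))
        assert p.sum() == 119 and f.sum() == 119

    def test_dropped_excluded_from_force_only(self):
        p, f = apply_exclusions(self._table(dropped=[5]))
        assert p.sum() == 120 and f.sum() == 119

    def test_non_analyzable_excluded_everywhere(self):
        df = self._table()
        df.loc[0, "analyzable"] = False
        p, f = apply_exclusions(df)
        assert p.sum() == 119 and f.sum() == 119

    def test_force_set_subset_of_perceptual(self, rng):
        df = self._table()
        for col in ("tms_failed", "dropped", "multiple_lifts", "not_lifted"):
            df.loc[rng.choice(120, 10, replace=False), col] = True
        p, f = apply_exclusions(df)
        assert (f & ~p).sum() == 0


class TestEndToEndRecovery:
    def test_noiseless_liftoff_recovery(self, noiseless_params, rng):
        p = noiseless_params
        for pair, prev, cur in (
            ("LL", "light", "light"), ("HL", "heavy", "light"),
            ("LH", "light", "heavy"), ("HH", "heavy", "heavy"),
        ):
            spec = TrialSpec(2, ObjectKind(cur), TmsCondition.NONE,
                             OrderPair(pair), True)
            res = simulate_trial(spec, ObjectKind(prev), p, rng)
            ev, m = metrics_from_trace(res.trace, p.object_weight(cur))
            assert m is not None
            assert abs(ev.t_liftoff - res.truth["t_liftoff"]) <= 0.002

    def test_gf_static_matches_coupling(self, noiseless_params, rng):
        p = noiseless_params
        spec = TrialSpec(2, ObjectKind.HEAVY, TmsCondition.NONE, OrderPair.HH, True)
        res = simulate_trial(spec, ObjectKind.HEAVY, p, rng)
        _, m = metrics_from_trace(res.trace, p.object_weight("heavy"))
        expect = p.gf_lf_ratio * p.object_weight("heavy") + p.safety_margin
        assert m.gf_static == pytest.approx(expect, abs=1e-3)

    def test_noisy_liftoff_recovery(self, rng):
        p = SimParams(noise_sd_force=0.05)
        ok = 0
        n = 60
        for i in range(n):
            spec = TrialSpec(2, ObjectKind.LIGHT, TmsCondition.NONE,
                             OrderPair.LL, True)
            res = simulate_trial(spec, ObjectKind.LIGHT, p, rng)
            ev, _ = metrics_from_trace(res.trace, p.object_weight("light"))
            if ev.lifted and abs(ev.t_liftoff - res.truth["t_liftoff"]) <= 0.010:
                ok += 1
        assert ok / n >= 0.95
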