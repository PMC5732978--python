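"""AP normalization and APD computation on constructed waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipsctailor.apmetrics import (
    DetectionError,
    apd_from_trace,
    compute_apd,
    detect_alternans,
    normalize_ap,
    summarize_population,
)
from ipsctailor.model import APTrace


def square_pulse(width_ms=200.0, total_ms=600.0, dt=0.5, lo=0.0, hi=1.0,
                 onset=100.0):
    t = np.arange(0.0, total_ms, dt)
    y = np.where((t >= onset) & (t < onset + width_ms), hi, lo)
    return APTrace(time_ms=t, signal=y.astype(float))


def triangle_ap(decay_ms=300.0, total_ms=600.0, dt=0.5, onset=100.0):
    """Instant upstroke to 1 then linear fall to 0 over decay_ms."""
    t = np.arange(0.0, total_ms, dt)
    y = np.zeros_like(t)
    falling = (t >= onset) & (t < onset + decay_ms)
    y[falling] = 1.0 - (t[falling] - onset) / decay_ms
    return APTrace(time_ms=t, signal=y)


class TestNormalize:
    def test_square_pulse_normalizes_to_itself(self):
        trace = square_pulse()
        norm = normalize_ap(trace)
        assert norm.baseline == pytest.approx(0.0, abs=1e-9)
        assert norm.amplitude == pytest.approx(1.0, rel=1e-6)
        np.testing.assert_allclose(norm.signal, trace.signal, atol=1e-9)

    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, gain, offset):
        base = square_pulse()
        shifted = APTrace(time_ms=base.time_ms,
                          signal=gain * base.signal + offset)
        n1 = normalize_ap(base)
        n2 = normalize_ap(shifted)
        np.testing.assert_allclose(n1.signal, n2.signal, atol=1e-9)

    def test_idempotent(self):
        norm = normalize_ap(square_pulse())
        again = normalize_ap(APTrace(time_ms=norm.time_ms, signal=norm.signal))
        np.testing.assert_allclose(norm.signal, again.signal, atol=1e-9)

    def test_flat_trace_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(DetectionError):
            normalize_ap(APTrace(time_ms=t, signal=np.zeros_like(t)))

    def test_simulated_peak_reaches_at_least_one(self, baseline_model):
        """A peaked waveform's maximum exceeds the 95th-percentile unit."""
        from ipsctailor.model import ModelParameterSet, PaciModel, simulate_paced
        from ipsctailor.tailoring import tailor_cell

        beat = simulate_paced(PaciModel(tailor_cell(1)), n_prebeats=10,
                              n_record_beats=1)[0]
        norm = normalize_ap(beat)
        assert norm.signal.max() >= 1.0


class TestAPD:
    def test_square_pulse_apd_equals_width(self):
        width = 200.0
        trace = square_pulse(width_ms=width)
        norm = normalize_ap(trace)
        for frac in (0.9, 0.5):
            apd = compute_apd(norm, frac)
            assert apd == pytest.approx(width, abs=1.0)

    def test_trapezoid_ap_closed_form(self):
        """Plateau + linear fall: APD_f = plateau + f * decay exactly.

        The plateau guarantees the 95th in-AP percentile equals the peak,
        so the normalized threshold crossings have a simple closed form."""
        plateau, decay, dt = 100.0, 300.0, 0.5
        t = np.arange(0.0, 700.0, dt)
        y = np.zeros_like(t)
        onset = 100.0
        y[(t >= onset) & (t < onset + plateau)] = 1.0
        falling = (t >= onset + plateau) & (t < onset + plateau + decay)
        y[falling] = 1.0 - (t[falling] - onset - plateau) / decay
        norm = normalize_ap(APTrace(time_ms=t, signal=y))
        assert compute_apd(norm, 0.9) == pytest.approx(plateau + 0.9 * decay,
                                                       abs=2.0)
        assert compute_apd(norm, 0.5) == pytest.approx(plateau + 0.5 * decay,
                                                       abs=2.0)

    def test_triangular_ap_percentile_aware_closed_form(self):
        """For a plateau-less triangle the in-AP samples are uniform, the
        95th percentile sits below the peak, and the crossing moves
        accordingly: APD_f = (1 - q95 * (1 - f)) * decay."""
        decay = 300.0
        norm = normalize_ap(triangle_ap(decay_ms=decay))
        q95 = norm.amplitude  # raw peak is 1, so amplitude == q95
        assert 0.90 < q95 < 1.0
        for frac in (0.9, 0.5):
            expected = (1.0 - q95 * (1.0 - frac)) * decay
            assert compute_apd(norm, frac) == pytest.approx(expected, abs=2.0)

    def test_apd90_not_less_than_apd50(self):
        norm = normalize_ap(triangle_ap())
        assert compute_apd(norm, 0.9) >= compute_apd(norm, 0.5)

    def test_failure_returns_none(self):
        # never repolarizes: stays at plateau after upstroke
        t = np.arange(0.0, 400.0, 0.5)
        y = np.where(t >= 100.0, 1.0, 0.0)
        norm = normalize_ap(APTrace(time_ms=t, signal=y))
        assert compute_apd(norm, 0.9) is None
        assert apd_from_trace(APTrace(time_ms=t, signal=y)).failure_flag

    def test_slowing_repolarization_increases_apd90(self):
        apds = [compute_apd(normalize_ap(triangle_ap(decay_ms=d)), 0.9)
                for d in (150.0, 250.0, 400.0)]
        assert apds[0] < apds[1] < apds[2]

    def test_bad_fraction_rejected(self):
        norm = normalize_ap(square_pulse())
        with pytest.raises(ValueError):
            compute_apd(norm, 1.5)


class TestAlternans:
    def test_constant_apds_not_flagged(self):
        flagged, sel = detect_alternans([300.0, 300.0, 300.0])
        assert not flagged and sel == 300.0

    def test_large_swing_flagged_selects_longer(self):
        flagged, sel = detect_alternans([200.0, 300.0], threshold=0.05)
        assert flagged and sel == 300.0

    def test_tiny_jitter_below_threshold(self):
        flagged, _ = detect_alternans([300.0, 300.2, 299.9], threshold=0.05)
        assert not flagged

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            detect_alternans([300.0])


class TestPopulationSummary:
    def test_median_of_three(self):
        out = summarize_population([1.0, 2.0, 3.0])
        assert out["median"] == 2.0

    def test_degenerate_population(self):
        out = summarize_population([5.0] * 7)
        assert out["q25"] == out["median"] == out["q75"] == 5.0

    @given(st.lists(st.floats(1.0, 1000.0), min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None)
    def test_percentiles_ordered(self, values):
        out = summarize_population(values)
        assert out["q25"] <= out["median"] <= out["q75"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_population([])
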