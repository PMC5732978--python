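"""Voltage-clamp protocols, superposition, masking and leak handling."""

import numpy as np
import pytest

from ipsctailor import _paci2013 as _k
from ipsctailor.clamp import (
    ClampConditions,
    CurrentTraceSet,
    apply_leak_correction,
    calcium_solution,
    holding_state,
    make_calcium_protocol,
    make_outward_protocol,
    make_sodium_protocol,
    peak_iv,
    simulate_voltage_clamp,
    sodium_solution,
)
from ipsctailor.model import ModelParameterSet, PaciModel


@pytest.mark.parametrize(
    "factory, n_steps, first, last, dur_ms, interval_s",
    [
        (make_sodium_protocol, 13, -60.0, 60.0, 20.0, 5.0),
        (make_calcium_protocol, 9, -40.0, 40.0, 200.0, 5.0),
        (make_outward_protocol, 10, -40.0, 50.0, 500.0, 10.0),
    ],
)
def test_protocol_definitions(factory, n_steps, first, last, dur_ms, interval_s):
    proto = factory()
    assert proto.n_steps == n_steps
    assert proto.step_potentials[0] == first
    assert proto.step_potentials[-1] == last
    assert proto.step_duration == dur_ms
    assert proto.interstep_interval == interval_s
    assert proto.holding_potential == -80.0
    assert proto.mask_after_change == 10.0


def test_mask_covers_post_change_window(outward_clamp):
    _, total = outward_clamp
    assert np.all(total.time_ms[~total.mask] >= 10.0)
    assert np.all(total.time_ms[total.mask] < 10.0)


def test_superposition_of_components(outward_clamp):
    """Total clamp current equals the sum of the component readouts."""
    components, total = outward_clamp
    sum_traces = sum(tr.data for tr in components.values())
    assert np.max(np.abs(sum_traces - total.data)) < 1e-10


def test_scale_readout_commutation(baseline_model):
    """Simulating with scale k equals k x the unit-scale component trace."""
    proto = make_sodium_protocol()
    sol = sodium_solution()
    unit, _ = simulate_voltage_clamp(baseline_model, proto, sol,
                                     components=("I_Kr",))
    scaled_model = PaciModel(ModelParameterSet(scale={"I_Kr": 3.5}))
    scaled, _ = simulate_voltage_clamp(scaled_model, proto, sol,
                                       components=("I_Kr",))
    a, b = scaled["I_Kr"].data, 3.5 * unit["I_Kr"].data
    denom = np.max(np.abs(b)) or 1.0
    assert np.max(np.abs(a - b)) / denom < 1e-8


def test_concentrations_clamped_during_sweep(baseline_model):
    """Under clamp, the concentration derivatives are identically zero."""
    proto = make_outward_protocol()
    sol = sodium_solution()
    y = holding_state(baseline_model, proto, sol)
    p = _k.pack_params(
        np.ones(12), temperature=sol.temperature, nao=sol.nao, ko=sol.ko,
        cao=sol.cao, ki=sol.ki, clamp_v=True, clamp_conc=True,
    )
    y[0] = 0.05
    dy = _k._rhs_py(0.0, y, p)
    assert dy[0] == 0.0  # Vm clamped
    assert dy[1] == dy[2] == dy[17] == 0.0  # Ca_SR, Cai, Nai clamped


def test_blocked_currents_forced_to_zero(baseline_model):
    proto = make_calcium_protocol()
    sol = calcium_solution()
    comps, _ = simulate_voltage_clamp(
        baseline_model, proto, sol, components=("I_Kr", "I_Ks", "I_CaL")
    )
    assert np.all(comps["I_Kr"].data == 0.0)
    assert np.all(comps["I_Ks"].data == 0.0)
    assert np.any(comps["I_CaL"].data != 0.0)


def test_unknown_blocked_current_rejected():
    with pytest.raises(ValueError):
        ClampConditions(nai=10, ki=110, cai=0, nao=150, ko=4, cao=1.2,
                        blocked_currents=frozenset({"I_nope"}))


def _flat_trace(value, n=50, steps=(-80.0, 0.0)):
    t = np.arange(n, dtype=float)
    data = np.full((n, len(steps)), value)
    return CurrentTraceSet(
        time_ms=t,
        step_potentials=np.array(steps),
        data=data,
        mask=t < 10.0,
    )


class TestLeakCorrection:
    def test_large_resistance_is_identity(self):
        trace = _flat_trace(1.0)
        out = apply_leak_correction(trace, 1e15)
        assert np.max(np.abs(out.data - trace.data)) < 1e-12

    def test_ohms_law_at_minus80(self):
        """-80 mV / 1 GOhm = -80 pA subtracted (A/F via capacitance)."""
        trace = _flat_trace(0.0, steps=(-80.0,))
        out = apply_leak_correction(trace, 1.0)
        expected_af = -80e-12 / (trace.capacitance_pF * 1e-12)
        assert out.data[0, 0] == pytest.approx(-expected_af)

    def test_pure_leak_trace_corrects_to_zero(self):
        steps = np.array([-40.0, 0.0, 40.0])
        t = np.arange(30, dtype=float)
        r = 2.0  # GOhm
        leak_af = (steps / r) * 1e-12 / 30e-12
        data = np.tile(leak_af, (t.size, 1))
        trace = CurrentTraceSet(time_ms=t, step_potentials=steps, data=data,
                                mask=t < 10)
        out = apply_leak_correction(trace, r)
        assert np.max(np.abs(out.data)) < 1e-12

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            apply_leak_correction(_flat_trace(0.0), 0.0)


class TestPeakIV:
    def test_monotone_ramp_peaks_at_window_end(self):
        t = np.arange(50, dtype=float)
        data = np.column_stack([t, 2 * t])
        trace = CurrentTraceSet(time_ms=t, step_potentials=np.array([0.0, 10.0]),
                                data=data, mask=t < 10)
        np.testing.assert_allclose(peak_iv(trace, "outward"), [49.0, 98.0])

    def test_all_zero_sweep(self):
        trace = _flat_trace(0.0)
        assert np.all(peak_iv(trace, "inward") == 0.0)

    def test_sodium_peak_same_step_as_total(self, sodium_clamp):
        """Simulated I_Na peaks at the same step potential as the total."""
        comps, total = sodium_clamp
        pk_na = peak_iv(comps["I_Na"], "inward", respect_mask=False)
        pk_tot = peak_iv(total, "inward", respect_mask=False)
        assert np.argmin(pk_na) == np.argmin(pk_tot)

    def test_bad_polarity_rejected(self):
        with pytest.raises(ValueError):
            peak_iv(_flat_trace(0.0), "sideways")
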