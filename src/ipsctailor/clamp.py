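"""Step voltage-clamp protocols and their simulation.

Three whole-cell step protocols (sodium, calcium, lumped outward current)
are defined, and simulated with membrane potential clamped to the command
value and ion concentrations clamped to the pipette/bath solution values.
Each sweep starts from the holding-potential steady state; the inter-step
interval (5-10 s in the experiments) is long enough for full recovery and
is therefore not integrated.

The first ``mask_after_change`` ms after every commanded potential change
are flagged in an analysis mask, mirroring the capacitance-artifact
exclusion window applied to real recordings. Simulated traces contain no
capacitance artifact, so analyses of simulated data may opt out of the
mask (``peak_iv(..., respect_mask=False)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _paci2013 as _k
from .model import PaciModel, SolverError, steady_state_at_holding

__all__ = [
    "StepProtocol",
    "ClampConditions",
    "CurrentTraceSet",
    "make_sodium_protocol",
    "make_calcium_protocol",
    "make_outward_protocol",
    "sodium_solution",
    "calcium_solution",
    "outward_solution",
    "simulate_voltage_clamp",
    "apply_leak_correction",
    "peak_iv",
]

CLAMP_TEMPERATURE = 298.0  # K; clamp experiments were at room temperature

# Nominal pipette free Ca2+: no calcium added, 10-20 mM EGTA buffering.
# Mapped as 0 (the kernels floor ion concentrations at 1e-6 mM).
_EGTA_FREE_CA = 0.0  # mM

POTASSIUM_CURRENTS = frozenset({"I_K1", "I_Kr", "I_Ks", "I_to", "I_f"})


@dataclass(frozen=True)
class StepProtocol:
    """A holding potential plus an evenly spaced family of voltage steps."""

    name: str
    holding_potential: float  # mV
    step_potentials: tuple  # mV, strictly increasing, constant increment
    step_duration: float  # ms
    interstep_interval: float  # s
    mask_after_change: float = 10.0  # ms
    sample_interval: float = 0.1  # ms

    def __post_init__(self):
        steps = np.asarray(self.step_potentials, dtype=float)
        if steps.size < 2:
            raise ValueError("need at least two step potentials")
        incs = np.diff(steps)
        if np.any(incs <= 0) or not np.allclose(incs, incs[0]):
            raise ValueError("step potentials must increase by a constant increment")
        if self.step_duration <= self.mask_after_change:
            raise ValueError("step_duration must exceed the masked window")
        if self.interstep_interval < 0:
            raise ValueError("interstep_interval must be >= 0")
        object.__setattr__(self, "step_potentials", tuple(steps))

    @property
    def n_steps(self) -> int:
        return len(self.step_potentials)

    def time_grid_ms(self) -> np.ndarray:
        n = int(round(self.step_duration / self.sample_interval))
        return np.linspace(0.0, self.step_duration, n + 1)


def make_sodium_protocol() -> StepProtocol:
    """20 ms steps from -60 to +60 mV (10 mV increments), held at -80 mV."""
    return StepProtocol(
        name="sodium",
        holding_potential=-80.0,
        step_potentials=tuple(np.arange(-60.0, 60.0 + 1, 10.0)),
        step_duration=20.0,
        interstep_interval=5.0,
        sample_interval=0.1,
    )


def make_calcium_protocol() -> StepProtocol:
    """200 ms steps from -40 to +40 mV; holding -80 mV (assumed, as sodium)."""
    return StepProtocol(
        name="calcium",
        holding_potential=-80.0,
        step_potentials=tuple(np.arange(-40.0, 40.0 + 1, 10.0)),
        step_duration=200.0,
        interstep_interval=5.0,
        sample_interval=0.1,
    )


def make_outward_protocol() -> StepProtocol:
    """500 ms steps from -40 to +50 mV with a 10 s inter-step interval."""
    return StepProtocol(
        name="outward",
        holding_potential=-80.0,
        step_potentials=tuple(np.arange(-40.0, 50.0 + 1, 10.0)),
        step_duration=500.0,
        interstep_interval=10.0,
        sample_interval=1.0,
    )


@dataclass(frozen=True)
class ClampConditions:
    """Pipette/bath ion concentrations (mM) plus pharmacological blocks."""

    nai: float
    ki: float
    cai: float
    nao: float
    ko: float
    cao: float
    blocked_currents: frozenset = frozenset()
    temperature: float = CLAMP_TEMPERATURE

    def __post_init__(self):
        for name in ("nai", "ki", "cai", "nao", "ko", "cao"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.blocked_currents) - set(_k.CURRENT_NAMES)
        if unknown:
            raise ValueError(f"unknown blocked currents: {sorted(unknown)}")
        object.__setattr__(
            self, "blocked_currents", frozenset(self.blocked_currents)
        )


def sodium_solution() -> ClampConditions:
    """Na/outward-experiment solutions: NaCl/KCl bath, KCl/KF pipette."""
    return ClampConditions(
        nai=10.0, ki=110.0, cai=_EGTA_FREE_CA, nao=150.0, ko=4.0, cao=1.2
    )


def outward_solution() -> ClampConditions:
    """Identical recipe to the sodium experiments."""
    return sodium_solution()


def calcium_solution() -> ClampConditions:
    """Cs/TEA pipette (K currents blocked), NMDG bath (Na-free), 2 mM Ca."""
    return ClampConditions(
        nai=8.2,  # Na2-ATP + Na-GTP
        ki=0.0,
        cai=_EGTA_FREE_CA,
        nao=0.0,
        ko=0.0,
        cao=2.0,
        blocked_currents=POTASSIUM_CURRENTS,
    )


@dataclass
class CurrentTraceSet:
    """Per-step-potential current samples on a shared uniform time grid.

    ``data`` has one column per step potential (A/F, or pA if ``units`` says
    so, with ``capacitance_pF`` giving the conversion). ``mask`` flags the
    samples inside the capacitance-artifact window after each commanded
    potential change (True = masked / excluded from analysis).
    """

    time_ms: np.ndarray
    step_potentials: np.ndarray
    data: np.ndarray  # (n_samples, n_steps)
    mask: np.ndarray  # (n_samples,) bool
    units: str = "A/F"
    capacitance_pF: float = 30.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.step_potentials = np.asarray(self.step_potentials, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.data.shape != (self.time_ms.size, self.step_potentials.size):
            raise ValueError("data shape mismatch")
        if self.mask.shape != self.time_ms.shape:
            raise ValueError("mask shape mismatch")

    def unmasked(self) -> np.ndarray:
        """Concatenated unmasked samples, sweep-major (step order)."""
        return self.data[~self.mask].T.ravel()

    def copy_with(self, data: np.ndarray) -> "CurrentTraceSet":
        return replace(self, data=np.asarray(data, dtype=float))


def _conditions_params(model: PaciModel, conditions: ClampConditions,
                       clamp_v: bool = True) -> np.ndarray:
    scales = model.params.scale_vector().copy()
    for name in conditions.blocked_currents:
        scales[_k.CURRENT_NAMES.index(name)] = 0.0
    return _k.pack_params(
        scales,
        temperature=conditions.temperature,
        nao=conditions.nao,
        ko=conditions.ko,
        cao=conditions.cao,
        ki=conditions.ki,
        clamp_v=clamp_v,
        clamp_conc=True,
    )


def holding_state(model: PaciModel, protocol: StepProtocol,
                  conditions: ClampConditions) -> np.ndarray:
    """Steady state at the protocol's holding potential under the solution."""
    clamp_model = PaciModel(
        replace(model.params, temperature=conditions.temperature)
    )
    y = steady_state_at_holding(
        clamp_model,
        protocol.holding_potential,
        nao=conditions.nao,
        ko=conditions.ko,
        cao=conditions.cao,
        ki=conditions.ki,
        nai=conditions.nai,
        cai=conditions.cai,
    )
    return y


def simulate_voltage_clamp(
    model: PaciModel,
    protocol: StepProtocol,
    conditions: ClampConditions,
    components: tuple = _k.CURRENT_NAMES,
    *,
    abs_tol: float = 1e-8,
    rel_tol: float = 1e-6,
):
    """Simulate a step protocol with V and ion concentrations clamped.

    Returns ``(component_traces, total_trace)`` where ``component_traces``
    maps each requested current name to its (scaled) trace. The total trace
    is the sum over *all* non-blocked currents, whether requested or not.
    Because the concentrations are clamped, the gating trajectory does not
    depend on the scale factors, and each component trace is exactly linear
    in its scale factor.
    """
    unknown = set(components) - set(_k.CURRENT_NAMES)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    p = _conditions_params(model, conditions)
    y0 = holding_state(model, protocol, conditions)

    t_ms = protocol.time_grid_ms()
    t_s = t_ms / 1000.0
    mask = t_ms < protocol.mask_after_change
    n_t, n_steps = t_ms.size, protocol.n_steps

    comp_data = np.zeros((12, n_t, n_steps))
    for s_idx, v_step in enumerate(protocol.step_potentials):
        y = y0.copy()
        y[0] = v_step / 1000.0
        sol = solve_ivp(
            lambda t, yy: _k._rhs(t, yy, p),
            (t_s[0], t_s[-1]),
            y,
            method="LSODA",
            t_eval=t_s,
            rtol=rel_tol,
            atol=abs_tol,
        )
        if not sol.success:  # pragma: no cover
            raise SolverError(
                f"sweep at {v_step:+.0f} mV failed: {sol.message}"
            )
        comp_data[:, :, s_idx] = _k._currents_traj(sol.y.T, p).T

    def _trace(arr, name):
        return CurrentTraceSet(
            time_ms=t_ms,
            step_potentials=np.asarray(protocol.step_potentials),
            data=arr,
            mask=mask.copy(),
            metadata={
                "protocol": protocol.name,
                "component": name,
                "temperature_K": conditions.temperature,
            },
        )

    component_traces = {
        name: _trace(comp_data[_k.CURRENT_NAMES.index(name)], name)
        for name in components
    }
    total = _trace(comp_data.sum(axis=0), "total")
    return component_traces, total


def apply_leak_correction(trace: CurrentTraceSet,
                          leak_resistance_gohm: float) -> CurrentTraceSet:
    """Subtract the ohmic seal leak I_leak = V / R_leak from every sweep.

    V is the commanded step potential of each sweep; the pA leak is
    converted to A/F with the trace's cell capacitance.
    """
    if leak_resistance_gohm <= 0:
        raise ValueError("leak resistance must be positive")
    leak_pA = trace.step_potentials / leak_resistance_gohm  # mV/GOhm = pA
    if trace.units == "pA":
        leak = leak_pA
    else:
        leak = leak_pA * 1e-12 / (trace.capacitance_pF * 1e-12)  # A/F
    corrected = trace.data - leak[np.newaxis, :]
    out = trace.copy_with(corrected)
    out.metadata = dict(trace.metadata, leak_corrected=True,
                        leak_resistance_GOhm=leak_resistance_gohm)
    return out


def peak_iv(trace: CurrentTraceSet, polarity: str,
            respect_mask: bool = True) -> np.ndarray:
    """Per-step extremal current of the requested polarity.

    ``polarity`` is ``"inward"`` (most negative) or ``"outward"`` (most
    positive). Masked samples are excluded by default; simulated traces
    carry no capacitance artifact and may be analyzed unmasked.
    """
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    sel = ~trace.mask if respect_mask else np.ones_like(trace.mask)
    if not np.any(sel):
        raise ValueError("no unmasked samples in the step window")
    window = trace.data[sel]
    return window.min(axis=0) if polarity == "inward" else window.max(axis=0)
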