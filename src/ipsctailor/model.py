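"""Baseline iPSC-CM action-potential model with linear conductance scaling.

Public surface of the model: a :class:`ModelParameterSet` holding one
dimensionless scale factor per membrane current, a :class:`PaciModel`
handle wrapping the transcribed ODE system, per-current readout, paced
simulation and holding-potential steady states.

Public interfaces use mV / ms / A/F / mM; the kernels run in the model's
native units (V, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _paci2013 as _k
from ._paci2013 import CURRENT_NAMES, STATE_NAMES

__all__ = [
    "CURRENT_NAMES",
    "STATE_NAMES",
    "ModelParameterSet",
    "CurrentVector",
    "APTrace",
    "PaciModel",
    "build_baseline_model",
    "compute_currents",
    "simulate_paced",
    "steady_state_at_holding",
]

DEFAULT_ABS_TOL = 1e-6
DEFAULT_REL_TOL = 1e-4


class ConfigurationError(ValueError):
    """Unknown current name or otherwise malformed model configuration."""


@dataclass(frozen=True)
class ModelParameterSet:
    """Per-current conductance scale factors plus global simulation settings.

    Attributes
    ----------
    scale
        Dimensionless multiplier per current name (every known current
        present; default 1.0 everywhere).
    temperature
        Kelvin. Enters reversal potentials, the L-type Ca driving term and
        the voltage-dependent factors of I_Kr activation, I_NaK and I_NaCa.
    stimulus_amplitude
        Depolarizing stimulus density in A/F.
    stimulus_duration
        ms.
    cycle_length
        Pacing period in seconds.
    """

    scale: dict = field(default_factory=dict)
    temperature: float = _k.T_DEFAULT
    stimulus_amplitude: float = _k.STIM_AMPLITUDE_DEFAULT
    stimulus_duration: float = _k.STIM_DURATION_DEFAULT * 1000.0
    cycle_length: float = 1.0

    def __post_init__(self):
        full = {name: 1.0 for name in CURRENT_NAMES}
        for name, value in self.scale.items():
            if name not in full:
                raise ConfigurationError(f"unknown current name: {name!r}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"scale[{name}] must be finite and >= 0")
            full[name] = float(value)
        object.__setattr__(self, "scale", full)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive (s)")

    def scale_vector(self) -> np.ndarray:
        return np.array([self.scale[name] for name in CURRENT_NAMES])

    def with_scales(self, **updates) -> "ModelParameterSet":
        new = dict(self.scale)
        new.update(updates)
        return replace(self, scale=new)


@dataclass(frozen=True)
class CurrentVector:
    """Per-current densities (A/F) and their sum at one state."""

    entries: dict
    total: float

    def __getitem__(self, name: str) -> float:
        return self.entries[name]


@dataclass
class APTrace:
    """A sampled membrane-potential trace (uniform grid)."""

    time_ms: np.ndarray
    signal: np.ndarray  # mV for simulated traces
    stimulus_times_ms: np.ndarray | None = None

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_ms.size < 2:
            raise ValueError("an AP trace needs at least two samples")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time grid must be strictly increasing")


class PaciModel:
    """Handle over the transcribed ODE system for one parameterization."""

    def __init__(self, params: ModelParameterSet | None = None):
        self.params = params or ModelParameterSet()

    @property
    def initial_state(self) -> np.ndarray:
        return _k.Y0.copy()

    def _pack(self, **kwargs) -> np.ndarray:
        kwargs.setdefault("temperature", self.params.temperature)
        return _k.pack_params(self.params.scale_vector(), **kwargs)

    def rhs(self, t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        return _k._rhs(t, y, p)

    def currents(self, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        return _k._currents(y, p)


def build_baseline_model(params: ModelParameterSet | None = None) -> PaciModel:
    """Build the baseline model, optionally with conductance overrides.

    With all scale factors 1.0 the right-hand side reproduces the published
    ventricular iPSC-CM formulation; every conductance / permeability is
    multiplied by its scale factor.
    """
    return PaciModel(params)


def compute_currents(
    state: np.ndarray,
    params: ModelParameterSet,
    *,
    nao: float = _k.NAO_DEFAULT,
    ko: float = _k.KO_DEFAULT,
    cao: float = _k.CAO_DEFAULT,
    ki: float = _k.KI_DEFAULT,
    stimulus: float = 0.0,
) -> CurrentVector:
    """Evaluate every membrane current density (A/F) at a fixed state.

    ``total`` is the plain sum of the twelve entries plus any active
    stimulus; it equals the total ionic current the membrane equation uses.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite model state")
    p = _k.pack_params(
        params.scale_vector(),
        temperature=params.temperature,
        nao=nao,
        ko=ko,
        cao=cao,
        ki=ki,
    )
    cur = _k._currents(state, p)
    entries = {name: float(cur[i]) for i, name in enumerate(CURRENT_NAMES)}
    return CurrentVector(entries=entries, total=float(cur.sum()) + stimulus)


def _integrate(p, y0, t_span, t_eval=None, abs_tol=DEFAULT_ABS_TOL,
               rel_tol=DEFAULT_REL_TOL, method="LSODA"):
    rhs = _k._rhs
    sol = solve_ivp(
        lambda t, y: rhs(t, y, p),
        t_span,
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
        max_step=np.inf,
    )
    if not sol.success:  # pragma: no cover - solver failure path
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol


class SolverError(RuntimeError):
    def __init__(self, message, beat_index=None):
        super().__init__(message)
        self.beat_index = beat_index


def simulate_paced(
    model: PaciModel,
    n_prebeats: int = 100,
    n_record_beats: int = 2,
    *,
    abs_tol: float = DEFAULT_ABS_TOL,
    rel_tol: float = DEFAULT_REL_TOL,
    dt_record_ms: float = 1.0,
    initial_state: np.ndarray | None = None,
) -> list[APTrace]:
    """Pace the model and return the recorded beats after conditioning.

    The stimulus is a square pulse at the start of each cycle; ion
    concentrations evolve freely under the model equations. Returns one
    membrane-potential :class:`APTrace` per recorded beat.
    """
    params = model.params
    cl = params.cycle_length
    stim_dur_s = params.stimulus_duration / 1000.0
    p = model._pack(
        stim_on=True,
        stim_amplitude=params.stimulus_amplitude,
        stim_start=0.0,
        stim_duration=stim_dur_s,
    )
    y = model.initial_state if initial_state is None else np.array(initial_state)

    # uniform recording grid over the whole beat, split at the stimulus edge
    t_all = np.arange(0.0, cl, dt_record_ms / 1000.0)
    # the stimulus edge itself is always evaluated so the second segment
    # starts from the exact edge state
    t_eval1 = np.unique(np.append(t_all[t_all < stim_dur_s], stim_dur_s))
    t_eval2 = t_all[t_all > stim_dur_s]

    traces: list[APTrace] = []
    for beat in range(n_prebeats + n_record_beats):
        record = beat >= n_prebeats
        try:
            # split at the stimulus edge so the solver never steps over it
            sol1 = _integrate(
                p, y, (0.0, stim_dur_s),
                t_eval=t_eval1 if record else None,
                abs_tol=abs_tol, rel_tol=rel_tol,
            )
            sol2 = _integrate(
                p, sol1.y[:, -1], (stim_dur_s, cl),
                t_eval=t_eval2 if record else None,
                abs_tol=abs_tol, rel_tol=rel_tol,
            )
        except RuntimeError as exc:
            raise SolverError(f"beat {beat}: {exc}", beat_index=beat) from exc
        if record:
            t_ms = np.concatenate([sol1.t, sol2.t]) * 1000.0
            vm_mv = np.concatenate([sol1.y[0], sol2.y[0]]) * 1000.0
            keep = np.concatenate([[True], np.diff(t_ms) > 0])
            traces.append(
                APTrace(
                    time_ms=t_ms[keep],
                    signal=vm_mv[keep],
                    stimulus_times_ms=np.array([0.0]),
                )
            )
        y = sol2.y[:, -1]
    return traces


def simulate_free_running(
    model: PaciModel,
    duration_s: float,
    *,
    dt_record_ms: float = 1.0,
    abs_tol: float = DEFAULT_ABS_TOL,
    rel_tol: float = DEFAULT_REL_TOL,
    method: str = "LSODA",
    initial_state: np.ndarray | None = None,
):
    """Unstimulated (spontaneous) simulation; returns (time_ms, states)."""
    p = model._pack()
    y0 = model.initial_state if initial_state is None else np.array(initial_state)
    t_eval = np.arange(0.0, duration_s, dt_record_ms / 1000.0)
    sol = _integrate(p, y0, (0.0, duration_s), t_eval=t_eval,
                     abs_tol=abs_tol, rel_tol=rel_tol, method=method)
    return sol.t * 1000.0, sol.y.T


class ConvergenceError(RuntimeError):
    pass


def steady_state_at_holding(
    model: PaciModel,
    holding_potential_mv: float,
    *,
    nao: float = _k.NAO_DEFAULT,
    ko: float = _k.KO_DEFAULT,
    cao: float = _k.CAO_DEFAULT,
    ki: float = _k.KI_DEFAULT,
    nai: float | None = None,
    cai: float | None = None,
    ca_sr: float | None = None,
    rate_tol: float = 1e-6,
    max_time_s: float = 1000.0,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Relax gating variables at a clamped membrane potential.

    Membrane potential and ion concentrations are held fixed; the gate ODEs
    are integrated until the maximum state derivative falls below
    ``rate_tol`` (1/s). Used to condition each voltage-clamp sweep.
    """
    if not -120.0 <= holding_potential_mv <= 60.0:
        raise ValueError("holding potential outside physiological range")
    p = _k.pack_params(
        model.params.scale_vector(),
        temperature=model.params.temperature,
        nao=nao,
        ko=ko,
        cao=cao,
        ki=ki,
        clamp_v=True,
        clamp_conc=True,
    )
    y = model.initial_state if initial_state is None else np.array(initial_state)
    y[0] = holding_potential_mv / 1000.0
    if nai is not None:
        y[17] = nai
    if cai is not None:
        y[2] = cai
    if ca_sr is not None:
        y[1] = ca_sr

    t, chunk = 0.0, 20.0
    while t < max_time_s:
        sol = _integrate(p, y, (0.0, chunk), abs_tol=1e-9, rel_tol=1e-8)
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(_k._rhs(0.0, y, p))) < rate_tol:
            return y
    raise ConvergenceError(
        f"no steady state at {holding_potential_mv} mV within {max_time_s}s"
    )
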