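"""Synthetic inputs with known ground truth.

Emulates SyncroPatch-style whole-cell recordings: a linear superposition of
scaled model component currents, plus an ohmic seal leak, a capacitance
transient after each commanded potential change, and additive Gaussian
noise. Also generates synthetic cell populations (log-uniform conductance
spread matching the observed per-cell scale-factor ranges) and
pseudo-optical AP traces (gain/offset/drift/noise on a voltage waveform).

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clamp import CurrentTraceSet, StepProtocol
from .decomposition import ComponentMatrix
from .model import APTrace

__all__ = [
    "SyntheticCellSpec",
    "synth_outward_trace",
    "synth_cell_population",
    "synth_optical_ap",
]

DEFAULT_ACCESS_RESISTANCE_MOHM = 10.0
DEFAULT_CAPACITANCE_TAU_MS = 1.0
DEFAULT_CAPACITANCE_PF = 30.0
DEFAULT_NOISE_FRACTION = 0.02  # of the robust (95th pct) signal amplitude


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Ground truth for one synthetic patch-clamp cell."""

    true_s: dict  # component name -> scale >= 0
    seed: int
    noise_sd: float | None = None  # A/F; None = 2% of robust amplitude
    leak_resistance: float | None = None  # GOhm; None = no leak
    capacitance_tau: float = DEFAULT_CAPACITANCE_TAU_MS  # ms
    access_resistance: float = DEFAULT_ACCESS_RESISTANCE_MOHM  # MOhm

    def __post_init__(self):
        if any(v < 0 for v in self.true_s.values()):
            raise ValueError("true scale factors must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.capacitance_tau <= 0:
            raise ValueError("capacitance_tau must be positive")


def synth_outward_trace(
    spec: SyntheticCellSpec,
    matrix: ComponentMatrix,
    protocol: StepProtocol | None = None,
    *,
    capacitance_pF: float = DEFAULT_CAPACITANCE_PF,
    add_transient: bool = True,
) -> CurrentTraceSet:
    """Synthesize a whole-cell recording of the matrix's protocol.

    trace = sum_i s_i * unit_component_i + V/R_leak + A exp(-t/tau) + noise,
    with the transient amplitude A = dV / R_access (converted to A/F) after
    the potential change that starts each sweep. The transient decays well
    within the 10 ms analysis mask by default.
    """
    protocol = protocol or matrix.protocol
    unknown = set(spec.true_s) - set(matrix.component_names)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")

    t_ms = np.unique(matrix.column_map[:, 1])
    steps = np.asarray(protocol.step_potentials)
    n_t, n_steps = t_ms.size, steps.size

    s = np.array([spec.true_s.get(n, 0.0) for n in matrix.component_names])
    clean = (s @ matrix.matrix_full).reshape(n_steps, n_t).T  # (n_t, n_steps)

    data = clean.copy()
    if spec.leak_resistance is not None:
        if spec.leak_resistance <= 0:
            raise ValueError("leak resistance must be positive")
        leak_pA = steps / spec.leak_resistance
        data = data + leak_pA[np.newaxis, :] * 1e-12 / (capacitance_pF * 1e-12)
    if add_transient:
        dv = steps - protocol.holding_potential  # mV
        amp_pA = dv / spec.access_resistance * 1e3  # mV/MOhm = nA -> pA
        amp_af = amp_pA * 1e-12 / (capacitance_pF * 1e-12)
        decay = np.exp(-t_ms / spec.capacitance_tau)
        data = data + decay[:, np.newaxis] * amp_af[np.newaxis, :]

    noise_sd = spec.noise_sd
    if noise_sd is None:
        robust_amp = np.percentile(np.abs(clean), 95)
        noise_sd = DEFAULT_NOISE_FRACTION * robust_amp
    rng = np.random.default_rng(spec.seed)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    mask = t_ms < protocol.mask_after_change
    return CurrentTraceSet(
        time_ms=t_ms,
        step_potentials=steps,
        data=data,
        mask=mask,
        capacitance_pF=capacitance_pF,
        metadata={
            "protocol": protocol.name,
            "synthetic": True,
            "seed": spec.seed,
            "noise_sd": float(noise_sd),
            "true_s": dict(spec.true_s),
        },
    )


def synth_cell_population(
    n: int,
    scale_ranges: dict,
    seed: int,
    **spec_kwargs,
) -> list[SyntheticCellSpec]:
    """Draw ``n`` synthetic cells with log-uniform scale factors.

    ``scale_ranges`` maps component name to (min, max); this mirrors the
    orders-of-magnitude inter-cell spread seen in the fitted population
    (e.g. s_Ks spanning 9.18-467 across 22 cells).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not scale_ranges:
        raise ValueError("scale_ranges is empty")
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n):
        true_s = {}
        for name, (lo, hi) in scale_ranges.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad range for {name}: {(lo, hi)}")
            true_s[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        cells.append(
            SyntheticCellSpec(
                true_s=true_s,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
                **spec_kwargs,
            )
        )
    return cells


def synth_optical_ap(
    source: APTrace,
    *,
    gain: float = 1.0,
    offset: float = 0.0,
    photon_noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 10_000.0,
) -> APTrace:
    """Emulate an optical-mapping fluorescence recording of a voltage trace.

    signal = gain * V(t) + offset + drift_slope * t + Gaussian noise,
    resampled to the optical sample rate (default 10 kHz). Arbitrary units;
    ground-truth APD is known from the noiseless source.
    """
    dt_ms = 1000.0 / sample_rate_hz
    t = np.arange(source.time_ms[0], source.time_ms[-1], dt_ms)
    v = np.interp(t, source.time_ms, source.signal)
    rng = np.random.default_rng(seed)
    signal = gain * v + offset + drift_slope * (t - t[0])
    if photon_noise_sd > 0:
        signal = signal + rng.normal(0.0, photon_noise_sd, size=t.size)
    return APTrace(time_ms=t, signal=signal,
                   stimulus_times_ms=source.stimulus_times_ms)
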