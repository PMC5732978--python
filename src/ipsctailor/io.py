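"""Delimited-text readers and writers for every artifact the pipeline uses.

Traces are CSV with a ``time_ms`` column plus one ``step_<mV>`` column per
sweep and a YAML side-car (``<name>.meta.yaml``) carrying cell id, protocol
name, leak resistance, capacitance and the masking window. Parameter sets,
fit results and APD tables are plain CSV/YAML; everything written here can
be read back by the functions in this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clamp import CurrentTraceSet
from .model import APTrace, ModelParameterSet

__all__ = [
    "write_trace",
    "read_trace",
    "write_params",
    "read_params",
    "write_state",
    "read_state",
    "write_fit_result",
    "read_fit_result",
    "write_ap_trace",
    "read_ap_trace",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_trace(trace: CurrentTraceSet, path) -> Path:
    path = Path(path)
    cols = {"time_ms": trace.time_ms}
    for k, v in enumerate(trace.step_potentials):
        cols[f"step_{v:g}"] = trace.data[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = dict(trace.metadata)
    meta.update(
        units=trace.units,
        capacitance_pF=float(trace.capacitance_pF),
        step_potentials=[float(v) for v in trace.step_potentials],
        mask_after_change_ms=float(
            trace.time_ms[~trace.mask][0] if trace.mask.any() else 0.0
        ),
    )
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_trace(path) -> CurrentTraceSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = yaml.safe_load(mp.read_text()) or {}
    time_ms = df["time_ms"].to_numpy()
    step_cols = [c for c in df.columns if c.startswith("step_")]
    steps = np.array([float(c[len("step_"):]) for c in step_cols])
    order = np.argsort(steps)
    data = df[step_cols].to_numpy()[:, order]
    mask_ms = float(meta.get("mask_after_change_ms", 10.0))
    return CurrentTraceSet(
        time_ms=time_ms,
        step_potentials=steps[order],
        data=data,
        mask=time_ms < mask_ms,
        units=meta.get("units", "A/F"),
        capacitance_pF=float(meta.get("capacitance_pF", 30.0)),
        metadata={k: v for k, v in meta.items()
                  if k not in ("units", "capacitance_pF", "step_potentials",
                               "mask_after_change_ms")},
    )


def write_params(params: ModelParameterSet, path) -> Path:
    path = Path(path)
    doc = {
        "scale": {k: float(v) for k, v in params.scale.items()},
        "temperature": float(params.temperature),
        "stimulus_amplitude": float(params.stimulus_amplitude),
        "stimulus_duration": float(params.stimulus_duration),
        "cycle_length": float(params.cycle_length),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_params(path) -> ModelParameterSet:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return ModelParameterSet(
        scale=doc.get("scale", {}),
        temperature=float(doc.get("temperature", 310.0)),
        stimulus_amplitude=float(
            doc.get("stimulus_amplitude",
                    ModelParameterSet().stimulus_amplitude)
        ),
        stimulus_duration=float(doc.get("stimulus_duration", 5.0)),
        cycle_length=float(doc.get("cycle_length", 1.0)),
    )


def write_state(state, path) -> Path:
    """Model state snapshot as one-row CSV with state-variable headers."""
    from .model import STATE_NAMES

    state = np.asarray(state, dtype=float)
    if state.size != len(STATE_NAMES):
        raise ValueError(f"state must have {len(STATE_NAMES)} entries")
    path = Path(path)
    pd.DataFrame([state], columns=list(STATE_NAMES)).to_csv(path, index=False)
    return path


def read_state(path) -> np.ndarray:
    from .model import STATE_NAMES

    df = pd.read_csv(Path(path))
    missing = set(STATE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"snapshot is missing state variables: {sorted(missing)}")
    return df[list(STATE_NAMES)].iloc[0].to_numpy(dtype=float)


def write_fit_result(result, path) -> Path:
    """Fit result as CSV (component, s, c) with metadata comment lines."""
    path = Path(path)
    lines = [
        f"# method: {result.method}",
        f"# seed: {result.seed}",
        f"# sse: {result.sse!r}",
        f"# seed_l2: {','.join(repr(v) for v in result.seed_l2)}",
        "component,s,c",
    ]
    for name in result.s:
        lines.append(f"{name},{result.s[name]!r},{result.c[name]!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fit_result(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")


def write_ap_trace(trace: APTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": trace.time_ms, "signal": trace.signal}).to_csv(
        path, index=False
    )
    return path


def read_ap_trace(path) -> APTrace:
    df = pd.read_csv(Path(path))
    return APTrace(time_ms=df["time_ms"].to_numpy(),
                   signal=df["signal"].to_numpy())
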