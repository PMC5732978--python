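"""Tailored per-cell models and Hill-equation drug block.

Tailoring applies (i) the cell-line-wide inward scalings estimated from the
peak-IV experiments (I_Na x 0.69, I_CaL x 0.80) and (ii) the per-cell
I_Ks / I_NaCa scale factors fitted from the outward-current recordings
(bundled fixture; a dash in the fitted table means the current was not
discernible, mapped to scale 0). All other currents keep their published
conductances, and no kinetics are altered.

Drug action scales each targeted current's maximum conductance by the Hill
factor f(x) = 1 / (1 + (x / IC50)^h); dose-response curves pace every
tailored model (plus the untailored original) at the compound-specific
cycle length and summarize APD90/APD50 over the non-excluded cells.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .apmetrics import apd_from_trace, detect_alternans
from .model import ModelParameterSet, PaciModel, simulate_paced

__all__ = [
    "INWARD_SCALE_NA",
    "INWARD_SCALE_CAL",
    "ALTERNANS_THRESHOLD",
    "DrugSpec",
    "DoseResponseCurve",
    "load_table2_fixture",
    "load_drug_library",
    "tailor_cell",
    "tailored_cell_ids",
    "hill_block",
    "apply_drug",
    "dose_response",
]

# Cell-line-wide inward-current scalings from the peak-IV experiments
INWARD_SCALE_NA = 0.69
INWARD_SCALE_CAL = 0.80

# Consecutive-beat relative APD90 difference above which alternans is
# "strong" and the cell is excluded from dose-response summaries.
ALTERNANS_THRESHOLD = 0.05


def _data_path(name: str):
    return resources.files("ipsctailor.data").joinpath(name)


def load_table2_fixture() -> pd.DataFrame:
    """The fitted per-cell scale factors and contribution scores (n = 22).

    Columns: cell, then s_<current> / c_<current> pairs for I_NaCa, I_Ks,
    I_Kr, I_K1, I_f. NaN marks a dash (scale below the 1e-10 reporting
    threshold, i.e. the current was not discernible in that recording).
    """
    with resources.as_file(_data_path("table2_scales.csv")) as path:
        df = pd.read_csv(path)
    if len(df) != 22:
        raise ValueError(f"scale-factor fixture has {len(df)} rows, expected 22")
    return df


def tailored_cell_ids() -> list[int]:
    return load_table2_fixture()["cell"].astype(int).tolist()


def tailor_cell(cell_id: int, table: pd.DataFrame | None = None,
                cycle_length: float = 1.0) -> ModelParameterSet:
    """Parameter set for one tailored cell model.

    scale[I_Na] = 0.69 and scale[I_CaL] = 0.80 (cell-line averages),
    scale[I_Ks] and scale[I_NaCa] from the cell's fitted row (absent -> 0);
    every other current keeps scale 1.0.
    """
    table = load_table2_fixture() if table is None else table
    row = table[table["cell"] == cell_id]
    if row.empty:
        raise KeyError(f"unknown cell id: {cell_id}")
    row = row.iloc[0]

    def _scale(col):
        v = row[col]
        return 0.0 if pd.isna(v) else float(v)

    return ModelParameterSet(
        scale={
            "I_Na": INWARD_SCALE_NA,
            "I_CaL": INWARD_SCALE_CAL,
            "I_Ks": _scale("s_Ks"),
            "I_NaCa": _scale("s_NaCa"),
        },
        cycle_length=cycle_length,
    )


@dataclass(frozen=True)
class DrugSpec:
    """A compound: per-current IC50 map (uM), Hill coefficient, tested
    concentrations (uM) and pacing cycle length (s). Currents absent from
    ``ic50`` are unaffected ("no significant effect")."""

    name: str
    ic50: dict
    concentrations: tuple
    cycle_length: float
    hill_coefficient: float = 1.0

    def __post_init__(self):
        if any(v <= 0 for v in self.ic50.values()):
            raise ValueError("IC50 values must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if self.hill_coefficient <= 0:
            raise ValueError("Hill coefficient must be positive")
        object.__setattr__(self, "concentrations", tuple(self.concentrations))


def load_drug_library() -> dict:
    """The bundled reference-drug table (four blockers + negative control)."""
    with resources.as_file(_data_path("table1_drugs.yaml")) as path:
        raw = yaml.safe_load(path.read_text())
    return {
        name: DrugSpec(
            name=name,
            ic50=entry.get("ic50", {}) or {},
            concentrations=tuple(entry["concentrations"]),
            cycle_length=float(entry["cycle_length"]),
            hill_coefficient=float(entry.get("hill_coefficient", 1.0)),
        )
        for name, entry in raw.items()
    }


def hill_block(x: float, ic50: float, h: float = 1.0) -> float:
    """Fraction of conductance remaining at drug concentration x (uM).

    f(x) = 1 / (1 + (x/IC50)^h); f(0) = 1 (no block), f(IC50) = 0.5,
    strictly decreasing in x.
    """
    if x < 0:
        raise ValueError("concentration must be >= 0")
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if h <= 0:
        raise ValueError("Hill coefficient must be positive")
    return 1.0 / (1.0 + (x / ic50) ** h)


def apply_drug(params: ModelParameterSet, drug: DrugSpec,
               x: float) -> ModelParameterSet:
    """New parameter set with each targeted conductance Hill-scaled.

    The input parameter set is unmodified; applying at x = 0 is the
    identity, and applying twice composes multiplicatively.
    """
    updates = {
        current: params.scale[current]
        * hill_block(x, ic50, drug.hill_coefficient)
        for current, ic50 in drug.ic50.items()
    }
    return params.with_scales(**updates)


@dataclass
class DoseResponseCurve:
    """Per-cell APDs and population summaries per tested concentration."""

    drug: str
    per_cell: pd.DataFrame  # concentration_uM, cell_id, apd90_ms, apd50_ms, excluded, reason
    summary: pd.DataFrame  # concentration_uM, median/q25/q75 apd90 + apd50, n_included


def _measure_model(params: ModelParameterSet, n_prebeats: int,
                   n_record_beats: int):
    """Pace one parameterization and reduce it to APD metrics + flags."""
    model = PaciModel(params)
    beats = simulate_paced(model, n_prebeats=n_prebeats,
                           n_record_beats=n_record_beats)
    results = [apd_from_trace(b) for b in beats]
    apd90s = [r.apd90 for r in results]
    apd50s = [r.apd50 for r in results]
    if any(a is None for a in apd90s):
        return None, None, False, "repolarization_failure"
    flagged, apd90 = detect_alternans(apd90s, ALTERNANS_THRESHOLD)
    _, apd50 = detect_alternans(apd50s, ALTERNANS_THRESHOLD)
    reason = "strong_alternans" if flagged else ""
    return apd90, apd50, flagged, reason


def dose_response(
    cells: dict,
    drug: DrugSpec,
    *,
    concentrations=None,
    include_control: bool = True,
    n_prebeats: int = 100,
    n_record_beats: int = 4,
) -> DoseResponseCurve:
    """Dose-response of APD90/APD50 over a set of cell models.

    ``cells`` maps a label (cell id or "original") to a
    :class:`ModelParameterSet`. Each model is paced at the drug's cycle
    length for ``n_prebeats`` conditioning beats; APDs are measured on the
    recorded beats (the longer of the final two under alternans). Cells
    with strong alternans or repolarization failure are flagged excluded
    and dropped from the summary percentiles.
    """
    concs = list(drug.concentrations if concentrations is None else concentrations)
    if include_control:
        concs = [0.0] + [c for c in concs if c > 0]

    rows = []
    for x in concs:
        for label, params in cells.items():
            paced = replace(params, cycle_length=drug.cycle_length)
            blocked = apply_drug(paced, drug, x)
            apd90, apd50, flagged, reason = _measure_model(
                blocked, n_prebeats, n_record_beats
            )
            rows.append(
                {
                    "drug": drug.name,
                    "concentration_uM": x,
                    "cell_id": label,
                    "apd90_ms": apd90,
                    "apd50_ms": apd50,
                    "excluded": bool(flagged or reason),
                    "reason": reason,
                }
            )
    per_cell = pd.DataFrame(rows)

    summaries = []
    for x, group in per_cell.groupby("concentration_uM"):
        ok = group[~group["excluded"] & group["cell_id"].ne("original")]
        entry = {"concentration_uM": x, "n_included": int(len(ok))}
        for col in ("apd90_ms", "apd50_ms"):
            vals = ok[col].to_numpy(dtype=float)
            if vals.size:
                q25, med, q75 = np.percentile(vals, [25, 50, 75])
            else:  # every cell excluded at this concentration
                q25 = med = q75 = np.nan
            stem = col.replace("_ms", "")
            entry |= {f"{stem}_median": med, f"{stem}_q25": q25, f"{stem}_q75": q75}
        summaries.append(entry)
    summary = pd.DataFrame(summaries).sort_values("concentration_uM",
                                                  ignore_index=True)
    return DoseResponseCurve(drug=drug.name, per_cell=per_cell, summary=summary)
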