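"""Figure-style outputs regenerated from the pipeline's data tables.

Plots are always rendered *from* the delimited tables the pipeline writes,
never the other way around, so every figure is reproducible from text
artifacts alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_baseline_population", "plot_dose_response"]


def plot_baseline_population(baseline: pd.DataFrame, path) -> Path:
    """Histogram of tailored-model APD90s with the original model marked."""
    path = Path(path)
    tailored = baseline[baseline["cell_id"] != "original"]
    apds = tailored["apd90_ms"].dropna().to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if apds.size:
        ax.hist(apds, bins=10, color="tab:orange", alpha=0.8,
                label="tailored models")
    original = baseline.loc[baseline["cell_id"] == "original", "apd90_ms"]
    if not original.empty and np.isfinite(original.iloc[0]):
        ax.axvline(float(original.iloc[0]), color="tab:blue", lw=2,
                   label="original model")
    ax.set_xlabel("APD$_{90}$ (ms)")
    ax.set_ylabel("cells")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_dose_response(summary: pd.DataFrame, drug: str, path) -> Path:
    """Median APD90 with interquartile band vs concentration."""
    path = Path(path)
    df = summary.sort_values("concentration_uM")
    doses = df["concentration_uM"].to_numpy(dtype=float)
    # show control (x = 0) at a decade below the lowest tested dose
    positive = doses[doses > 0]
    x = np.where(doses > 0, doses,
                 positive.min() / 10.0 if positive.size else 1.0)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(x, df["apd90_q25"], df["apd90_q75"],
                    color="tab:orange", alpha=0.3, label="25th-75th pct")
    ax.plot(x, df["apd90_median"], "o-", color="tab:orange", label="median")
    ax.set_xscale("log")
    ax.set_xlabel(f"{drug} concentration (uM)")
    ax.set_ylabel("APD$_{90}$ (ms)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
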