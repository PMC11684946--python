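"""Figure generation for sweep results and sensitivity tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .experiments import fit_regression

_TARGETS = {"mean_capillary_speed_mm_s": "mean capillary speed (mm/s)",
            "pressure_drop_mmhg": "pressure drop (mmHg)"}


def plot_sweep(df: pd.DataFrame, path, model_sets=("sym_number", "sym_diameter")):
    """Replicate-level targets vs arteriolar cross-sectional area with OLS lines."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
    colors = plt.cm.tab10(np.linspace(0, 1, 10))
    for ax, (col, label) in zip(axes, _TARGETS.items()):
        for k, ms in enumerate(model_sets):
            sub = df[(df["model_set"] == ms) & df[col].notna()]
            ax.plot(sub["A_art"], sub[col], "o", ms=4, color=colors[k], label=ms)
            target = "velocity" if col.startswith("mean") else "pressure_drop"
            fit = fit_regression(df, target, ms)
            xs = np.linspace(sub["A_art"].min(), sub["A_art"].max(), 50)
            ax.plot(xs, fit.intercept + fit.slope * xs, "-", color=colors[k], lw=1)
        ax.set_xlabel("arteriolar cross-sectional area A (µm²)")
        ax.set_ylabel(label)
        ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_sensitivity(tables: dict, path):
    """One panel per varied parameter: both targets vs the parameter value."""
    n = len(tables)
    fig, axes = plt.subplots(1, n, figsize=(3.6 * n, 3.2), squeeze=False)
    for ax, (param, df) in zip(axes[0], tables.items()):
        ax.plot(df["value"], df["mean_capillary_speed_mm_s"], "o-",
                label="speed (mm/s)", ms=3)
        ax2 = ax.twinx()
        ax2.plot(df["value"], df["pressure_drop_mmhg"], "s--", color="tab:red",
                 label="Δp (mmHg)", ms=3)
        ax.set_xlabel(param)
        ax.set_ylabel("mean capillary speed (mm/s)")
        ax2.set_ylabel("pressure drop (mmHg)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
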