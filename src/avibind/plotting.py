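"""Optional static figures for sweeps, sensitivity tables and avidity maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_dose_sweep", "plot_sensitivity", "plot_avidity_map"]


def plot_dose_sweep(frame: pd.DataFrame, path: str) -> None:
    """Metric curves vs dose from a dose_sweep table."""
    fig, ax = plt.subplots(figsize=(6, 4))
    biv = frame[frame["valency"] == "bivalent"]
    for col, label in [("a1_frac", "monovalent fraction"), ("a2_frac", "bivalent fraction"),
                       ("occupancy", "occupancy"), ("bound_ratio", "bound/antigen")]:
        ax.semilogx(biv["ainit"], biv[col], label=label)
    mono = frame[frame["valency"] == "monovalent"]
    if len(mono):
        ax.semilogx(mono["ainit"], mono["bound_ratio"], "--", label="bound/antigen (one-armed)")
    ax.set_xlabel("antibody dose (M)")
    ax.set_ylabel("equilibrium value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sensitivity(table: pd.DataFrame, output: str, path: str) -> None:
    """Grouped bars of total-order indices per dose for one output."""
    sub = table[table["output"] == output]
    doses = sorted(sub["ainit"].unique())
    params = list(sub["parameter"].unique())
    width = 0.8 / len(params)
    fig, ax = plt.subplots(figsize=(7, 4))
    for j, param in enumerate(params):
        vals = [sub[(sub["ainit"] == d) & (sub["parameter"] == param)]["ST"].iloc[0]
                for d in doses]
        errs = [sub[(sub["ainit"] == d) & (sub["parameter"] == param)]["ST_err"].iloc[0]
                for d in doses]
        x = np.arange(len(doses)) + (j - len(params) / 2 + 0.5) * width
        ax.bar(x, vals, width=width, yerr=errs, label=param)
    ax.set_xticks(np.arange(len(doses)), [f"{d:.0e}" for d in doses], fontsize=8)
    ax.set_xlabel("antibody dose (M)")
    ax.set_ylabel(f"total-order index, {output}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_avidity_map(frame: pd.DataFrame, path: str) -> None:
    """Heatmap of ΔEC50 over (rtot, KD)."""
    pivot = frame.pivot(index="rtot", columns="kd", values="delta_ec50")
    fig, ax = plt.subplots(figsize=(5.5, 4))
    mesh = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, shading="nearest")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("KD (M)")
    ax.set_ylabel("antigens per cell")
    fig.colorbar(mesh, label=r"$\Delta$EC50 (log10)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
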