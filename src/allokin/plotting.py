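"""Convenience plots for scan results (tables are the contract, plots are aids)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_gain_surface", "plot_inhibition_surface", "plot_landscape_pairs"]


def plot_gain_surface(table: pd.DataFrame, path, logy: bool = True) -> None:
    """Gain vs alpha, one line per modulator concentration."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for conc, grp in table.groupby("conc_M"):
        grp = grp.sort_values("alpha")
        ax.plot(grp["alpha"], grp["gain"], label=f"[M] = {conc:g} M")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel("gain (fold)")
    if logy:
        ax.set_yscale("log")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_inhibition_surface(table: pd.DataFrame, path) -> None:
    """Normalized uptake vs alpha, one line per modulator concentration."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for conc, grp in table.groupby("conc_M"):
        grp = grp.sort_values("alpha")
        ax.plot(grp["alpha"], grp["normalized_uptake"], label=f"[M] = {conc:g} M")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel("normalized uptake")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_landscape_pairs(table: pd.DataFrame, path) -> None:
    """Rate-constant pairs vs alpha with the LFER-compliant range shaded."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = table.sort_values("alpha")
    ax.plot(t["alpha"], t["k_fw"], color="tab:red", label="forward")
    ax.plot(t["alpha"], t["k_bw"], color="tab:green", label="backward")
    ax.axvspan(0.0, 1.0, color="0.85", zorder=0)
    ax.set_yscale("log")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel(r"rate constant (s$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
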