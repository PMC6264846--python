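"""Convenience plots of sweep tables (rates vs C/N, fixation maps)."""

from __future__ import annotations

import matplotlib.pyplot as plt
import pandas as pd


def plot_rates_vs_cn(table: pd.DataFrame, ax=None):
    """Protein-specific fixation rate against the C/N supply ratio.

    One curve per oxygen level; expects a single-ammonium sweep table.
    """
    if ax is None:
        _, ax = plt.subplots()
    for o2, sub in table.groupby("o2_fraction"):
        sub = sub.sort_values("c_over_n")
        ax.plot(sub["c_over_n"], sub["n_fixation_per_protein"], label=f"{o2:.0%} O$_2$")
    ax.set_xlabel("C/N supply ratio (mol sucrose / mol N)")
    ax.set_ylabel("N$_2$ fixation (mol N (g protein)$^{-1}$ h$^{-1}$)")
    ax.legend()
    return ax


def plot_carbon_allocation(table: pd.DataFrame, ax=None):
    """Stacked carbohydrate-allocation budget against C/N at one oxygen level."""
    if ax is None:
        _, ax = plt.subplots()
    sub = table.sort_values("c_over_n")
    cols = [c for c in sub.columns if c.startswith("alloc_")]
    ax.stackplot(
        sub["c_over_n"],
        [sub[c] for c in cols],
        labels=[c.removeprefix("alloc_").replace("_", " ") for c in cols],
    )
    ax.set_xlabel("C/N supply ratio (mol sucrose / mol N)")
    ax.set_ylabel("sucrose flux (mol m$^{-3}$ h$^{-1}$)")
    ax.legend(loc="upper left", fontsize="small")
    return ax
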