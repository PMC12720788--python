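"""Headless-safe plotting: Wood's plots and uptake curves.

Every number shown in a plot is also available from the corresponding
table function; plots are presentation artifacts only.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_woods", "plot_uptake_curve"]


def plot_woods(table: pd.DataFrame, ax=None, cmap: str = "coolwarm"):
    """Wood's plot: one horizontal bar per peptide segment and timepoint
    at its delta-HDX%, with dotted lines at the +/- threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    times = sorted(table["exposure_s"].unique())
    colors = plt.get_cmap(cmap)(np.linspace(0.1, 0.9, len(times)))
    for color, t in zip(colors, times):
        sub = table[table["exposure_s"] == t]
        for row in sub.itertuples():
            ax.hlines(
                row.delta_pct, row.start, row.end, color=color, linewidth=2,
                label=f"{t:g} s" if row.Index == sub.index[0] else None,
            )
    thr = float(table["threshold_pct"].iloc[0])
    ax.axhline(thr, linestyle=":", color="grey")
    ax.axhline(-thr, linestyle=":", color="grey")
    ax.axhline(0, color="black", linewidth=0.5)
    ax.set_xlabel("residue number")
    ax.set_ylabel(r"$\Delta$HDX (%)")
    a = table.attrs.get("condition_a", "A")
    b = table.attrs.get("condition_b", "B")
    ax.set_title(f"{b} $-$ {a}")
    ax.legend(fontsize=8)
    return ax


def plot_uptake_curve(
    records: pd.DataFrame, start: int, end: int, fit_table: pd.DataFrame | None = None, ax=None
):
    """Observed replicate uptake points per state for one peptide on a
    log-time axis, with fitted one-exponential curves overlaid when a fit
    table is supplied."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = records[(records["start"] == start) & (records["end"] == end)]
    if sub.empty:
        raise ValueError(f"peptide {start}-{end} not in records")
    for (variant, ligand), grp in sub.groupby(["variant", "ligand"]):
        nz = grp[grp["exposure_s"] > 0]
        pts = ax.plot(
            nz["exposure_s"], nz["relative_uptake_pct"], "o", ms=4,
            label=f"{variant}:{ligand}",
        )
        if fit_table is not None:
            fit = fit_table[
                (fit_table["start"] == start)
                & (fit_table["end"] == end)
                & (fit_table["variant"] == variant)
                & (fit_table["ligand"] == ligand)
            ]
            if not fit.empty:
                t = np.geomspace(nz["exposure_s"].min() / 2, nz["exposure_s"].max(), 200)
                row = fit.iloc[0]
                ax.plot(
                    t, row["amplitude"] * -np.expm1(-row["k_hdx_s"] * t),
                    "-", color=pts[0].get_color(), linewidth=1,
                )
    ax.set_xscale("log")
    ax.set_xlabel("exposure (s)")
    ax.set_ylabel("relative uptake (%)")
    ax.set_title(f"peptide {start}-{end}")
    ax.legend(fontsize=8)
    return ax
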