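"""Developmental-curve figures: treatment-ratio curves over DIV per
parameter and sex, with the BMR band shaded around the control curve,
asterisks on significant (above-BMR) cells and open symbols on
sex-specific ones.  Vector output (SVG/PDF)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import CONTROL_COMPOUND

__all__ = ["plot_parameter_curves", "plot_report"]


def plot_parameter_curves(
    ratio_df: pd.DataFrame,
    band: pd.DataFrame,
    flags: pd.DataFrame,
    parameter: str,
    compound: str,
    out_path,
) -> Path:
    """One figure per parameter x compound: male and female panels."""
    sexes = sorted(ratio_df["sex"].unique())
    fig, axes = plt.subplots(1, len(sexes), figsize=(5 * len(sexes), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    sub = ratio_df[
        (ratio_df["parameter"] == parameter)
        & ratio_df["compound"].isin([compound, CONTROL_COMPOUND])
        & ~ratio_df["outlier"]
        & ratio_df["ratio_pct"].notna()
    ]
    for ax, sex in zip(axes, sexes):
        ssub = sub[sub["sex"] == sex]
        b = band[(band["parameter"] == parameter) & (band["sex"] == sex)].sort_values("div")
        if len(b):
            ax.fill_between(b["div"], b["lower_pct"], b["upper_pct"], color="0.85", label="BMR")
        for conc, g in ssub.groupby("concentration_um"):
            curve = g.groupby("div")["ratio_pct"].agg(["mean", "sem"]).reset_index()
            label = "control" if conc == 0 else f"{conc:g} µM"
            ax.errorbar(curve["div"], curve["mean"], yerr=curve["sem"], marker="o",
                        ms=3, capsize=2, label=label)
            if conc != 0 and len(flags):
                f = flags[
                    (flags["parameter"] == parameter)
                    & (flags["compound"] == compound)
                    & (flags["concentration_um"] == conc)
                    & (flags["sex"] == sex)
                ]
                sig = f[f["significant"]]
                for _, row in sig.iterrows():
                    y = curve.loc[curve["div"] == row["div"], "mean"]
                    if len(y):
                        ax.annotate("*", (row["div"], float(y.iloc[0])), fontsize=12,
                                    ha="center", va="bottom")
                for _, row in f[f["sex_specific"]].iterrows():
                    y = curve.loc[curve["div"] == row["div"], "mean"]
                    if len(y):
                        ax.plot(row["div"], float(y.iloc[0]), marker="o", mfc="none",
                                mec="k", ms=9, ls="none")
        ax.set_title(f"{compound} — {sex}")
        ax.set_xlabel("DIV")
    axes[0].set_ylabel(f"{parameter} (% of control at final DIV)")
    axes[-1].legend(fontsize=7, frameon=False)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def plot_report(ratio_df, band, flags, out_dir, parameters=None) -> list[Path]:
    """Write one SVG per (parameter, compound) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = parameters or sorted(ratio_df["parameter"].unique())
    compounds = sorted(set(ratio_df["compound"]) - {CONTROL_COMPOUND})
    paths = []
    for compound in compounds:
        for p in params:
            paths.append(
                plot_parameter_curves(ratio_df, band, flags, p, compound,
                                      out / f"{compound}_{p}.svg")
            )
    return paths
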