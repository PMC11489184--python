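"""Dose-response statistics for chronic MEA exposure experiments.

Stages, in the order they are applied:

1. well inclusion — only wells with at least four bursting electrodes at
   the DIV 7 baseline recording are analyzed (for all their DIVs);
2. cumulative treatment ratios — per well and parameter, raw values are
   summed over recording days and expressed as a percentage of the mean
   cumulative value of the sex-matched solvent controls at the final DIV
   (so the control curve ends at exactly 100%);
3. outlier exclusion — values beyond mean +/- 2 x SD of their own
   (parameter, compound, concentration, sex, DIV) group are flagged once
   (no re-iteration) and removed from all downstream means and tests;
4. benchmark-response (BMR) band — control mean +/- pooled control SD per
   (parameter, sex, DIV); statistically significant deviations smaller
   than the band are of limited toxicological relevance and not flagged;
5. ANOVA — one-way across concentrations (Tukey HSD versus control) per
   parameter, sex and DIV; two-way concentration x sex (Type-II sums of
   squares, robust to the unbalanced well counts) with Tukey contrasts for
   sex-specificity at each concentration;
6. effect flags and LOEC — a cell is an effect iff Tukey p <= alpha AND
   the deviation from control exceeds the BMR half-width; the LOEC per
   compound and sex is the lowest concentration ever flagged.

The ratio table is a tidy frame with one row per (experiment, well,
parameter, DIV): columns compound, concentration_um, sex, cumulative_raw,
ratio_pct, outlier.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import PARAMETERS

__all__ = [
    "include_wells",
    "cumulative_ratios",
    "exclude_outliers",
    "bmr_band",
    "anova_oneway",
    "anova_twoway",
    "flag_and_summarize",
    "EffectReport",
    "CONTROL_COMPOUND",
]

log = logging.getLogger(__name__)

CONTROL_COMPOUND = "DMSO"
GROUP_COLS = ["parameter", "compound", "concentration_um", "sex", "div"]


# ---------------------------------------------------------------- inclusion

def include_wells(metrics_df: pd.DataFrame, baseline_div: int = 7, min_bursting: int = 4) -> pd.DataFrame:
    """Keep only wells with >= ``min_bursting`` bursting electrodes at baseline.

    A well failing the baseline requirement is dropped for the whole
    experiment (all DIVs).  Returns the filtered metrics table.
    """
    base = metrics_df[metrics_df["div"] == baseline_div]
    ok = base.loc[base["n_bursting_electrodes"] >= min_bursting, ["experiment", "well"]]
    keys = set(map(tuple, ok.itertuples(index=False)))
    mask = [
        (e, w) in keys for e, w in zip(metrics_df["experiment"], metrics_df["well"])
    ]
    kept = metrics_df[mask].copy()
    n_all = metrics_df[["experiment", "well"]].drop_duplicates().shape[0]
    log.info("well inclusion: retained %d of %d wells", len(keys), n_all)
    return kept


# ------------------------------------------------------- outlier exclusion

def exclude_outliers(
    table: pd.DataFrame,
    group_cols: list[str] = GROUP_COLS,
    value_col: str = "ratio_pct",
    n_sd: float = 2.0,
    min_group: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Flag values beyond mean +/- ``n_sd`` x sample SD of their group.

    A single pass (no re-iteration) using the sample SD (ddof=1).  Groups
    smaller than ``min_group`` are left untouched (SD unstable).  Returns
    the table with a boolean ``outlier`` column and the overall flagged
    fraction among non-missing values.
    """
    out = table.copy()
    vals = out[value_col]
    g = vals.groupby([out[c] for c in group_cols], dropna=False)
    m = g.transform("mean")
    s = g.transform("std")  # sample SD, ddof=1
    n = g.transform("count")
    with np.errstate(invalid="ignore"):
        flagged = ((vals - m).abs() > n_sd * s) & (n >= min_group) & (s > 0)
    out["outlier"] = flagged.fillna(False).astype(bool)
    n_valid = int(vals.notna().sum())
    frac = float(out.loc[vals.notna(), "outlier"].sum() / n_valid) if n_valid else 0.0
    log.info("outlier exclusion: flagged %.2f%% of %d values", 100 * frac, n_valid)
    return out, frac


# ------------------------------------------------------- cumulative ratios

def cumulative_ratios(
    metrics_df: pd.DataFrame,
    final_div: int = 28,
    parameters: tuple[str, ...] = PARAMETERS,
) -> tuple[pd.DataFrame, float]:
    """Cumulative treatment-ratio table, normalized to control at the final DIV.

    Per (well, parameter) the raw values are summed over recording days; a
    provisional ratio divides by the sex-matched control mean cumulative
    value at ``final_div``; outliers are then excluded per condition and
    DIV, and the controls are renormalized so that the mean retained
    control ratio at the final DIV is exactly 100%.  A missing raw value
    makes later cumulative values of that well/parameter missing too —
    undefined means are never imputed.

    Returns (ratio table, overall outlier fraction).
    """
    id_cols = ["experiment", "well", "compound", "concentration_um", "sex", "div"]
    long = metrics_df.melt(
        id_vars=id_cols, value_vars=list(parameters), var_name="parameter", value_name="raw"
    )
    long = long.sort_values(id_cols[:2] + ["parameter", "div"], kind="stable").reset_index(drop=True)
    long["cumulative_raw"] = (
        long.groupby(["experiment", "well", "parameter"], sort=False)["raw"]
        .transform(lambda s: np.cumsum(s.to_numpy()))  # NaN propagates
    )

    is_ctrl = long["compound"] == CONTROL_COMPOUND
    ctrl_final = long[is_ctrl & (long["div"] == final_div)]
    denom = (
        ctrl_final.groupby(["sex", "parameter"])["cumulative_raw"].mean().rename("ctrl_cum_final")
    )
    long = long.join(denom, on=["sex", "parameter"])
    missing = long["ctrl_cum_final"].isna() | (long["ctrl_cum_final"] == 0)
    if missing.any():
        for sex, param in (
            long.loc[missing, ["sex", "parameter"]].drop_duplicates().itertuples(index=False)
        ):
            log.warning("no usable control baseline for sex=%s parameter=%s; ratios undefined", sex, param)
    long["ratio_pct"] = 100.0 * long["cumulative_raw"] / long["ctrl_cum_final"]

    long, frac = exclude_outliers(long)

    # renormalize: retained control mean at the final DIV -> exactly 100%
    keep = is_ctrl & (long["div"] == final_div) & ~long["outlier"] & long["ratio_pct"].notna()
    ctrl_mean = long[keep].groupby(["sex", "parameter"])["ratio_pct"].mean().rename("ctrl_mean_final")
    long = long.join(ctrl_mean, on=["sex", "parameter"])
    long["ratio_pct"] = long["ratio_pct"] * (100.0 / long["ctrl_mean_final"])
    cols = id_cols[:2] + ["compound", "concentration_um", "sex", "div", "parameter",
                          "cumulative_raw", "ratio_pct", "outlier"]
    return long[cols].copy(), frac


# --------------------------------------------------------------- BMR band

def bmr_band(ratio_df: pd.DataFrame, mode: str = "per_div") -> pd.DataFrame:
    """Benchmark-response band from pooled solvent-control variability.

    Per (parameter, sex, DIV): control mean +/- half-width, where the
    half-width is the SD of retained control ratios pooled across control
    experiments at that DIV (``mode='per_div'``) or the time-averaged
    control SD over all DIVs (``mode='time_averaged'``).
    """
    ctrl = ratio_df[
        (ratio_df["compound"] == CONTROL_COMPOUND)
        & ~ratio_df["outlier"]
        & ratio_df["ratio_pct"].notna()
    ]
    g = ctrl.groupby(["parameter", "sex", "div"])["ratio_pct"]
    band = g.agg(control_mean="mean", half_width=lambda x: x.std(ddof=1)).reset_index()
    band["half_width"] = band["half_width"].fillna(0.0)
    if mode == "time_averaged":
        avg = band.groupby(["parameter", "sex"])["half_width"].transform("mean")
        band["half_width"] = avg
    elif mode != "per_div":
        raise ValueError("mode must be 'per_div' or 'time_averaged'")
    band["lower_pct"] = band["control_mean"] - band["half_width"]
    band["upper_pct"] = band["control_mean"] + band["half_width"]
    return band


# ------------------------------------------------------------------ ANOVA

@dataclass(frozen=True)
class OneWayResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # columns group1, group2, meandiff, p_adj


def tukey_hsd(arrays: list[np.ndarray], labels: list) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons on the studentized range.

    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)), with the adjusted
    p from the studentized-range distribution with k groups and the pooled
    within-group df.  Valid for unequal group sizes (Kramer's extension).
    """
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    dfw = int(ns.sum() - k)
    msw = sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)) / dfw
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        if msw > 0:
            q = abs(diff) / math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            p_adj = float(sps.studentized_range.sf(q, k, dfw))
        else:
            p_adj = 1.0 if diff == 0 else 0.0
        rows.append({"group1": str(labels[i]), "group2": str(labels[j]),
                     "meandiff": float(diff), "p_adj": p_adj})
    return pd.DataFrame(rows)


def anova_oneway(groups: dict) -> OneWayResult:
    """Classical fixed-effects one-way ANOVA with Tukey HSD post-hoc tests."""
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("anova_oneway needs >= 2 groups with >= 2 observations each")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("anova_oneway is undefined for identical constant groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    tukey = tukey_hsd(arrays, labels)
    return OneWayResult(F=float(F), df_between=k - 1, df_within=n - k, p=float(p), tukey=tukey)


@dataclass(frozen=True)
class TwoWayResult:
    table: pd.DataFrame  # Type-II ANOVA table (sum_sq, df, F, PR(>F))
    sex_contrasts: pd.DataFrame  # per concentration: meandiff (male - female), p_adj


def anova_twoway(df: pd.DataFrame, value_col: str = "ratio_pct") -> TwoWayResult:
    """Two-way fixed-effects ANOVA, factors concentration x sex, Type-II SS.

    Unbalanced designs are allowed; empty factor cells are dropped with a
    warning.  Sex-specificity at a concentration is read off the
    Tukey-adjusted male-versus-female contrast within that concentration
    (adjusted over all concentration x sex cell pairs).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = df[["concentration_um", "sex", value_col]].dropna().copy()
    d.columns = ["conc", "sex", "y"]
    counts = d.groupby(["conc", "sex"]).size()
    full = pd.MultiIndex.from_product([d["conc"].unique(), d["sex"].unique()])
    empty = full.difference(counts.index)
    if len(empty):
        log.warning("two-way ANOVA: dropping empty cells %s", list(empty))
        ok_conc = {c for c, s in counts.index}
        d = d[d["conc"].isin(ok_conc)]
    if d["conc"].nunique() < 2 or d["sex"].nunique() < 2:
        raise ValueError("two-way ANOVA needs >= 2 levels of both factors")
    model = smf.ols("y ~ C(conc) * C(sex)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    cell = d["conc"].astype(str) + "|" + d["sex"]
    labels = sorted(cell.unique())
    arrays = [d.loc[cell == lab, "y"].to_numpy() for lab in labels]
    tukey = tukey_hsd(arrays, labels)
    rows = []
    for _, r in tukey.iterrows():
        c1, s1 = r["group1"].rsplit("|", 1)
        c2, s2 = r["group2"].rsplit("|", 1)
        if c1 == c2 and s1 != s2:
            sign = 1.0 if (s2 == "male") else -1.0  # report male - female
            rows.append({"concentration_um": float(c1), "meandiff": sign * r["meandiff"],
                         "p_adj": r["p_adj"]})
    return TwoWayResult(table=table, sex_contrasts=pd.DataFrame(rows))


# ------------------------------------------------------ flags and summary

@dataclass
class EffectReport:
    """Per-cell significance flags, sex-specificity, and the LOEC summary.

    ``flags`` has one row per (parameter, compound, concentration, sex,
    DIV) with the one-way F/df/p, the Tukey-adjusted p versus control, the
    deviation from the control mean, the BMR half-width, and the derived
    booleans.  ``loec`` has one row per (compound, sex).
    """

    flags: pd.DataFrame
    loec: pd.DataFrame
    alpha: float = 0.05
    notes: list = field(default_factory=list)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "alpha": self.alpha,
                "flags": self.flags.to_dict(orient="records"),
                "loec": self.loec.to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )


def _direction(diff: float) -> str:
    return "excitation" if diff > 0 else "inhibition"


def flag_and_summarize(
    ratio_df: pd.DataFrame,
    band: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> EffectReport:
    """Apply the significance + BMR rule per cell and summarize LOECs.

    A cell (parameter, compound, concentration, sex, DIV) is significant
    iff its Tukey-adjusted p versus the sex-matched control is <= alpha AND
    the absolute deviation of its mean ratio from the control mean exceeds
    the BMR half-width.  Sex-specificity of a concentration comes from the
    two-way concentration x sex Tukey contrast.  The LOEC per (compound,
    sex) is the lowest concentration with >= 1 significant parameter at
    >= 1 DIV, with direction given by the sign of the flagged deviations.
    """
    df = ratio_df[~ratio_df["outlier"] & ratio_df["ratio_pct"].notna()]
    if band is None:
        band = bmr_band(ratio_df)
    bkey = band.set_index(["parameter", "sex", "div"])
    compounds = sorted(set(df["compound"]) - {CONTROL_COMPOUND})
    rows = []
    notes: list[str] = []
    for compound in compounds:
        sub_all = df[df["compound"].isin([compound, CONTROL_COMPOUND])]
        for parameter in sorted(df["parameter"].unique()):
            psub = sub_all[sub_all["parameter"] == parameter]
            for div in sorted(psub["div"].unique()):
                dsub = psub[psub["div"] == div]
                # sex-specific contrasts from the two-way layout (both sexes)
                sex_p: dict[float, float] = {}
                try:
                    tw = anova_twoway(dsub)
                    sex_p = dict(
                        zip(tw.sex_contrasts["concentration_um"], tw.sex_contrasts["p_adj"])
                    )
                except ValueError as exc:
                    notes.append(f"{compound}/{parameter}/DIV{div}: two-way skipped ({exc})")
                for sex in sorted(dsub["sex"].unique()):
                    ssub = dsub[dsub["sex"] == sex]
                    groups = {
                        conc: g["ratio_pct"].to_numpy()
                        for conc, g in ssub.groupby("concentration_um")
                    }
                    if 0.0 not in groups:
                        continue
                    try:
                        ow = anova_oneway(groups)
                    except ValueError as exc:
                        notes.append(f"{compound}/{parameter}/{sex}/DIV{div}: one-way skipped ({exc})")
                        continue
                    ctrl_mean = float(np.mean(groups[0.0]))
                    try:
                        hw = float(bkey.loc[(parameter, sex, div), "half_width"])
                        band_ctrl = float(bkey.loc[(parameter, sex, div), "control_mean"])
                    except KeyError:
                        hw, band_ctrl = np.nan, ctrl_mean
                    for conc in sorted(c for c in groups if c != 0.0):
                        tk = ow.tukey
                        m = tk[
                            ((tk["group1"] == str(conc)) & (tk["group2"] == str(0.0)))
                            | ((tk["group1"] == str(0.0)) & (tk["group2"] == str(conc)))
                        ]
                        p_vs_ctrl = float(m["p_adj"].iloc[0]) if len(m) else np.nan
                        diff = float(np.mean(groups[conc])) - band_ctrl
                        exceeds = bool(np.isfinite(hw) and abs(diff) > hw)
                        significant = bool(p_vs_ctrl <= alpha and exceeds)
                        rows.append(
                            {
                                "parameter": parameter,
                                "compound": compound,
                                "concentration_um": conc,
                                "sex": sex,
                                "div": div,
                                "F": ow.F,
                                "df_between": ow.df_between,
                                "df_within": ow.df_within,
                                "p_anova": ow.p,
                                "p_vs_control": p_vs_ctrl,
                                "diff_from_control": diff,
                                "bmr_half_width": hw,
                                "exceeds_bmr": exceeds,
                                "significant": significant,
                                "direction": _direction(diff) if significant else "",
                                "sex_specific": bool(sex_p.get(conc, np.nan) <= alpha),
                            }
                        )
    flags = pd.DataFrame(rows)
    loec_rows = []
    for compound in compounds:
        for sex in sorted(df["sex"].unique()):
            if len(flags):
                sig = flags[
                    (flags["compound"] == compound) & (flags["sex"] == sex) & flags["significant"]
                ]
            else:
                sig = pd.DataFrame()
            if len(sig) == 0:
                loec_rows.append(
                    {"compound": compound, "sex": sex, "loec_um": np.nan, "direction": "no effect"}
                )
            else:
                loec = sig["concentration_um"].min()
                at = sig[sig["concentration_um"] == loec]
                net = np.sign(at["diff_from_control"]).sum()
                loec_rows.append(
                    {
                        "compound": compound,
                        "sex": sex,
                        "loec_um": float(loec),
                        "direction": _direction(1.0 if net >= 0 else -1.0),
                    }
                )
    return EffectReport(flags=flags, loec=pd.DataFrame(loec_rows), alpha=alpha, notes=notes)
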