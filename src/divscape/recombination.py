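"""Diversity versus recombination rate.

Per-population Spearman correlations between windowed S and the mean
population-scaled recombination rate (rho_rec = 2Nr) of the same 5-kb
windows; an F-test for whether the correlation strength differs between
invasive and native populations; and the recombination-quantile scaled
difference statistic: windows are filtered to a native-range mean-S band,
binned by recombination-rate quantile, and the per-bin invasive-minus-
native difference in mean S — raw and scaled by the bin's overall mean S —
is correlated with the bin's recombination rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import diversity_wide

__all__ = [
    "load_recmap",
    "diversity_rec_correlation",
    "scaled_diff_by_rec_quantile",
]


def load_recmap(path_or_df, windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load and validate a windowed recombination map.

    Expects columns contig / window_start / window_end / mean_rho.
    Rejects negative rates and duplicated windows; when a window grid is
    supplied, every grid window must be present (mismatches are listed).
    """
    rec = (path_or_df.copy() if isinstance(path_or_df, pd.DataFrame)
           else pd.read_csv(path_or_df, sep="\t"))
    required = {"contig", "window_start", "window_end", "mean_rho"}
    if not required.issubset(rec.columns):
        raise ValueError(f"recombination map must have columns {sorted(required)}")
    if (rec["mean_rho"] < 0).any():
        raise ValueError("negative recombination rates in map")
    key = rec[["contig", "window_start"]]
    if key.duplicated().any():
        raise ValueError("duplicate windows in recombination map")
    if windows is not None:
        want = set(zip(windows["contig"], windows["start"]))
        have = set(zip(rec["contig"], rec["window_start"]))
        miss = sorted(want - have)
        if miss:
            raise ValueError(f"recombination map missing windows: {miss[:10]}"
                             + ("..." if len(miss) > 10 else ""))
    return rec.reset_index(drop=True)


def _join_rho(wide: pd.DataFrame, recmap: pd.DataFrame) -> pd.DataFrame:
    rho = pd.Series(recmap["mean_rho"].to_numpy(),
                    index=pd.MultiIndex.from_arrays(
                        [recmap["contig"], recmap["window_start"]],
                        names=["contig", "start"]))
    out = wide.copy()
    out["mean_rho"] = rho.reindex(wide.index)
    n_drop = int(out["mean_rho"].isna().sum())
    if n_drop:
        warnings.warn(f"{n_drop} windows lack a recombination estimate; excluded")
    return out.dropna(subset=["mean_rho"])


def diversity_rec_correlation(tables: dict, recmap: pd.DataFrame,
                              invasion_status: dict | None = None):
    """Per-population Spearman rho of S with recombination rate.

    With ``invasion_status`` (population -> invasive/native) and >= 2
    populations per status, a one-way linear model of rho on status is
    fit and its F statistic and p-value reported.
    """
    import statsmodels.formula.api as smf

    wide = _join_rho(diversity_wide(tables, "S"), recmap)
    rows = []
    for pop in tables:
        sub = wide[[pop, "mean_rho"]].dropna()
        r = stats.spearmanr(sub[pop], sub["mean_rho"])
        rows.append({"population": pop, "spearman_rho": float(r.statistic),
                     "p_value": float(r.pvalue), "n_windows": len(sub)})
    per_pop = pd.DataFrame(rows)
    result = {"per_population": per_pop, "f_stat": None, "f_pvalue": None}
    if invasion_status is not None:
        per_pop = per_pop.assign(status=per_pop["population"].map(invasion_status))
        if per_pop["status"].isna().any():
            raise ValueError("invasion_status missing for some populations")
        if per_pop.groupby("status").size().min() >= 2:
            fit = smf.ols("spearman_rho ~ C(status)", data=per_pop).fit()
            result["f_stat"] = float(fit.fvalue)
            result["f_pvalue"] = float(fit.f_pvalue)
            result["per_population"] = per_pop
    return result


def scaled_diff_by_rec_quantile(invasive_tables: dict, native_tables: dict,
                                recmap: pd.DataFrame, s_range=(150, 300),
                                n_bins: int = 20):
    """Quantile-binned scaled invasive-native difference in S.

    Windows are kept when the across-native-population mean S lies in
    ``s_range``; retained windows are split into ``n_bins`` equal-count
    bins of recombination rate.  Per bin: Delta = mean_invasive(S) -
    mean_native(S), scaled by the bin's overall mean S (all populations
    pooled).  Returns a dict with the per-bin table and Spearman
    correlations of the scaled and raw Delta with the bin mean
    recombination rate.
    """
    wide_inv = diversity_wide(invasive_tables, "S")
    wide_nat = diversity_wide(native_tables, "S")
    df = pd.DataFrame({
        "mean_inv": wide_inv.mean(axis=1),
        "mean_nat": wide_nat.mean(axis=1),
        "mean_all": pd.concat([wide_inv, wide_nat], axis=1).mean(axis=1),
    }).dropna()
    df = _join_rho(df, recmap)
    df = df[(df["mean_nat"] >= s_range[0]) & (df["mean_nat"] <= s_range[1])]
    if len(df) < n_bins:
        raise ValueError(f"only {len(df)} windows in S range; fewer than n_bins")
    # equal-count quantile bins on rank of rho (ties broken by order)
    order = np.argsort(np.argsort(df["mean_rho"].to_numpy(), kind="stable"))
    df = df.assign(bin=(order * n_bins // len(df)).astype(int))
    per_bin = (df.groupby("bin")
                 .agg(mean_rho=("mean_rho", "mean"),
                      mean_inv=("mean_inv", "mean"),
                      mean_nat=("mean_nat", "mean"),
                      mean_s=("mean_all", "mean"),
                      n_windows=("mean_all", "size"))
                 .reset_index())
    if len(per_bin) < n_bins:
        warnings.warn(f"reduced bin count: {len(per_bin)} of {n_bins} non-empty")
    per_bin["delta_raw"] = per_bin["mean_inv"] - per_bin["mean_nat"]
    per_bin["delta_scaled"] = per_bin["delta_raw"] / per_bin["mean_s"]
    if per_bin["delta_scaled"].nunique() > 1:
        r_s = stats.spearmanr(per_bin["delta_scaled"], per_bin["mean_rho"])
        r_r = stats.spearmanr(per_bin["delta_raw"], per_bin["mean_rho"])
        rho_scaled, rho_raw = float(r_s.statistic), float(r_r.statistic)
        p_scaled, p_raw = float(r_s.pvalue), float(r_r.pvalue)
    else:  # identical tables: all deltas equal, correlation undefined
        rho_scaled = rho_raw = float("nan")
        p_scaled = p_raw = float("nan")
    return {"per_bin": per_bin, "rho_scaled": rho_scaled, "rho_raw": rho_raw,
            "p_scaled": p_scaled, "p_raw": p_raw, "n_windows": len(df)}
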