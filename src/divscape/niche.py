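"""Association between genetic diversity and thermal-niche parameters.

Ordinary least squares of each derived thermal-niche parameter (B_50,
A_c, T_optimum) on a population's median windowed S, across populations
or restricted to one designated population per species (the subset that
sidesteps phylogenetic non-independence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_population_summaries", "fit_niche_diversity_models"]

NICHE_PARAMS = ("b_50", "a_c", "t_optimum")


def build_population_summaries(diversity_tables: dict, posterior,
                               species: dict | None = None,
                               invasion_status: dict | None = None) -> pd.DataFrame:
    """One row per population: median windowed S + posterior-median niche params."""
    rows = []
    for pop, tab in diversity_tables.items():
        row = {"population": pop, "median_S": float(tab["S"].median())}
        if species:
            row["species"] = species.get(pop)
        if invasion_status:
            row["status"] = invasion_status.get(pop)
        for name in NICHE_PARAMS:
            row[name] = float(np.median(posterior.draws[pop][name]))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_niche_diversity_models(summaries: pd.DataFrame, subset: str = "all",
                               one_per_species: dict | None = None) -> pd.DataFrame:
    """OLS of each niche parameter on median S; returns F, p, R^2, slope.

    ``subset="one-per-species"`` keeps the designated population per
    species (``one_per_species``: species -> population id); requires a
    ``species`` column.  A constant predictor is handled gracefully
    (F = 0, p = 1, slope NaN).
    """
    import statsmodels.formula.api as smf

    df = summaries.copy()
    if subset == "one-per-species":
        if "species" not in df.columns:
            raise ValueError("subset mode needs a 'species' column")
        if one_per_species is None:
            df = df.groupby("species", as_index=False).first()
        else:
            df = df[df["population"].isin(one_per_species.values())]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'one-per-species'")
    if len(df) < 4:
        raise ValueError("need >= 4 populations for the linear models")

    rows = []
    for name in NICHE_PARAMS:
        if df["median_S"].nunique() == 1:
            rows.append({"parameter": name, "slope": float("nan"), "f_stat": 0.0,
                         "p_value": 1.0, "r_squared": 0.0, "n": len(df),
                         "df_resid": len(df) - 2})
            continue
        fit = smf.ols(f"{name} ~ median_S", data=df).fit()
        rows.append({"parameter": name, "slope": float(fit.params["median_S"]),
                     "f_stat": float(fit.fvalue), "p_value": float(fit.f_pvalue),
                     "r_squared": float(fit.rsquared), "n": len(df),
                     "df_resid": int(fit.df_resid)})
    return pd.DataFrame(rows)
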