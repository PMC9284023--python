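"""Observed peak summaries and pairwise marginal-mean contrasts.

For every cage series (one cage in one period) the observed Cmax and Tmax
are read straight off the measured concentrations — no model involved.
Group differences between cage sizes are then summarised as pairwise
contrasts of estimated marginal means from a linear mixed model with a
random sheep intercept (``response ~ cage-size factor + (1 | sheep)``),
with Wald confidence intervals and, by design, no multiplicity adjustment
(a Holm option is available).
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["observed_peaks", "summarize_peaks", "emm_contrasts"]

_SERIES_KEYS = ["sheep_id", "period", "side", "length_cm"]


def observed_peaks(records: pd.DataFrame) -> pd.DataFrame:
    """Observed Tmax/Cmax per cage series.

    Pre-dose records are excluded; Cmax is the maximum observed
    concentration and Tmax the *earliest* sampling time attaining it (the
    documented tie-break).  Raises if any series has no post-dose
    observation.
    """
    df = records.loc[
        (records["matrix"] == "cage") & (~records["below_dose_time"].astype(bool))
        & (records["time_h"] >= 0)
    ]
    empty = set(
        map(tuple, records.loc[records["matrix"] == "cage", _SERIES_KEYS].drop_duplicates().values)
    ) - set(map(tuple, df[_SERIES_KEYS].drop_duplicates().values))
    if empty:
        raise ValueError(f"cage series with no post-dose observations: {sorted(empty)[:5]}")
    rows = []
    for key, grp in df.groupby(_SERIES_KEYS, sort=True):
        cmax = grp["conc_ug_ml"].max()
        tmax = grp.loc[grp["conc_ug_ml"] == cmax, "time_h"].min()
        rows.append(
            dict(
                zip(_SERIES_KEYS, key),
                carr_cage=bool(grp["carr_cage"].any()),
                tmax_h=float(tmax),
                cmax_ug_ml=float(cmax),
            )
        )
    return pd.DataFrame(rows)


def summarize_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Count, median, min and max of Tmax and Cmax per cage length.

    Medians use the usual midpoint convention for even counts.
    """
    if peaks.empty:
        raise ValueError("no peaks to summarise")
    out = (
        peaks.groupby("length_cm")
        .agg(
            count=("cmax_ug_ml", "size"),
            tmax_median=("tmax_h", "median"),
            tmax_min=("tmax_h", "min"),
            tmax_max=("tmax_h", "max"),
            cmax_median=("cmax_ug_ml", "median"),
            cmax_min=("cmax_ug_ml", "min"),
            cmax_max=("cmax_ug_ml", "max"),
        )
        .reset_index()
    )
    return out


def emm_contrasts(
    peaks: pd.DataFrame,
    response: str = "cmax",
    mixed: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise cage-size contrasts of estimated marginal means.

    Fits ``response ~ 0 + C(length_cm)`` with a random intercept per sheep
    (set ``mixed=False`` for a plain fixed-effects fit) and returns every
    pairwise difference of the size-level marginal means with Wald 95% CIs
    and p-values.  ``holm=True`` applies a Holm correction to the p-values
    (off by default, matching the unadjusted presentation of such tables).
    """
    col = {"cmax": "cmax_ug_ml", "tmax": "tmax_h"}.get(response, response)
    if col not in peaks.columns:
        raise ValueError(f"unknown response {response!r}")
    counts = peaks.groupby("length_cm")[col].size()
    small = counts[counts < 2]
    if len(small):
        logger.warning("dropping size groups with <2 observations: %s", list(small.index))
        peaks = peaks[~peaks["length_cm"].isin(small.index)]
    levels = np.sort(peaks["length_cm"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 cage-size groups")
    y = peaks[col].to_numpy(dtype=float)
    X = np.column_stack([(peaks["length_cm"] == lev).astype(float) for lev in levels])
    if mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=peaks["sheep_id"].to_numpy()).fit(reml=True)
        means = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: len(levels), : len(levels)]
    else:
        res = sm.OLS(y, X).fit()
        means = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
    rows = []
    z = stats.norm.ppf(0.975)
    for i, j in itertools.combinations(range(len(levels)), 2):
        L = np.zeros(len(levels)); L[i] = 1.0; L[j] = -1.0
        est = float(L @ means)
        se = float(np.sqrt(L @ cov @ L))
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
        rows.append(
            {
                "contrast": f"{levels[i]:g}-{levels[j]:g}",
                "estimate": est,
                "se": se,
                "ci_low": est - z * se,
                "ci_high": est + z * se,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if holm:
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_holm"] = adj
    return table
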