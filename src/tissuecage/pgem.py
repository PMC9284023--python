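"""Linear mixed-effects analysis of prostaglandin-E metabolite (PGEM) data.

PGEM concentrations measured in tissue-cage fluid are modelled on the log10
scale as a linear function of time since dosing, cage size (a 5-level
factor with the 3 cm cage as reference), and their interaction, with a
random intercept per sheep:

    log10(PGEM)_ij = beta0 + gamma_i + beta1*t_ij + beta2[size] +
                     beta3[size]*t_ij + eps_ij,

    gamma_i ~ N(0, sd_sheep^2),  eps_ij ~ N(0, sd_resid^2).

Fitting is by REML through :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
Explained variance is summarised by the Nakagawa marginal/conditional R²:
the marginal R² uses the fixed-effect variance only, the conditional R²
adds the random-intercept variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PgemModel",
    "PgemFit",
    "reference_pgem_model",
    "fit_pgem_lme",
    "nakagawa_r2",
    "solve_variance_components",
    "predict_pgem_curve",
    "CAGE_SIZE_LEVELS",
]

CAGE_SIZE_LEVELS = (3, 6, 10, 14, 18)
_NONREF_LEVELS = CAGE_SIZE_LEVELS[1:]


@dataclass(frozen=True)
class PgemModel:
    """Coefficients and variance components of the log10-PGEM mixed model.

    ``beta_size`` and ``beta_interaction`` map the non-reference cage sizes
    (6, 10, 14, 18 cm) to their offsets from the 3 cm reference level.
    ``sd_sheep``/``sd_resid`` may be ``None`` for a model whose variance
    components are to be calibrated later (see
    :func:`solve_variance_components`).
    """

    beta0: float
    beta_time: float
    beta_size: dict[int, float]
    beta_interaction: dict[int, float]
    sd_sheep: float | None = None
    sd_resid: float | None = None

    def __post_init__(self) -> None:
        for d, label in ((self.beta_size, "beta_size"), (self.beta_interaction, "beta_interaction")):
            if sorted(d) != sorted(_NONREF_LEVELS):
                raise ValueError(f"{label} must have exactly the levels {_NONREF_LEVELS}")
        if self.sd_sheep is not None and self.sd_sheep < 0:
            raise ValueError("sd_sheep must be >= 0")
        if self.sd_resid is not None and self.sd_resid <= 0:
            raise ValueError("sd_resid must be > 0")

    def linear_predictor(self, length_cm, time_h):
        """Population-level (random effects at zero) log10-PGEM prediction."""
        length_cm = np.asarray(length_cm)
        time_h = np.asarray(time_h, dtype=float)
        out = np.full(np.broadcast(length_cm, time_h).shape, self.beta0, dtype=float)
        out = out + self.beta_time * time_h
        for lev in _NONREF_LEVELS:
            mask = length_cm == lev
            out = out + np.where(mask, self.beta_size[lev] + self.beta_interaction[lev] * time_h, 0.0)
        known = np.isin(length_cm, CAGE_SIZE_LEVELS)
        if not np.all(known):
            raise ValueError(f"unknown cage-size level(s): {np.unique(np.asarray(length_cm)[~known])}")
        return out


def reference_pgem_model() -> PgemModel:
    """Published fixed-effect estimates of the sheep tissue-cage PGEM model
    (log10 pg/mL scale).  Variance components were not reported and are
    left unset; they are calibrated from the reported marginal/conditional
    R² pair (0.27, 0.42) when the model is used for simulation."""
    return PgemModel(
        beta0=1.55,
        beta_time=0.00731,
        beta_size={6: 0.0158, 10: 0.0664, 14: 0.169, 18: 0.0644},
        beta_interaction={6: 0.00800, 10: -0.00160, 14: -0.00416, 18: -0.00501},
    )


@dataclass
class PgemFit:
    """Result of a PGEM mixed-model fit (coefficients, table, variance)."""

    model: PgemModel
    table: pd.DataFrame          # term, estimate, se, ci_low, ci_high, p_value
    var_fixed: float             # variance of the fixed-effect predictor over the data
    loglik: float
    n_obs: int
    n_sheep: int
    converged: bool


def _design_matrix(length_cm: np.ndarray, time_h: np.ndarray) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(time_h), time_h]
    names = ["(Intercept)", "Time"]
    for lev in _NONREF_LEVELS:
        cols.append((length_cm == lev).astype(float))
        names.append(f"CageSizeFac{lev}")
    for lev in _NONREF_LEVELS:
        cols.append((length_cm == lev) * time_h)
        names.append(f"Time:CageSizeFac{lev}")
    return np.column_stack(cols), names


def fit_pgem_lme(records: pd.DataFrame) -> PgemFit:
    """REML fit of the log10-PGEM mixed model.

    ``records`` needs columns ``sheep_id``, ``length_cm``, ``time_h`` and
    ``pgem_pg_ml`` (natural scale; the log10 transform is applied here).
    Wald 95% CIs and p-values for the fixed effects use the normal
    reference distribution.
    """
    required = {"sheep_id", "length_cm", "time_h", "pgem_pg_ml"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    bad = records.index[records["pgem_pg_ml"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive PGEM values at rows {list(bad[:10])}")
    if records["sheep_id"].nunique() < 2:
        raise ValueError("need >= 2 sheep")
    if records["time_h"].nunique() < 2:
        raise ValueError("need >= 2 time points")

    y = np.log10(records["pgem_pg_ml"].to_numpy(dtype=float))
    X, names = _design_matrix(
        records["length_cm"].to_numpy(), records["time_h"].to_numpy(dtype=float)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = sm.MixedLM(y, X, groups=records["sheep_id"].to_numpy())
        res = mod.fit(reml=True)

    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    z = stats.norm.ppf(0.975)
    pvals = 2 * stats.norm.sf(np.abs(fe / se))
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": fe,
            "se": se,
            "ci_low": fe - z * se,
            "ci_high": fe + z * se,
            "p_value": pvals,
        }
    )
    var_sheep = float(np.asarray(res.cov_re)[0, 0])
    if var_sheep < 0:  # singular fits can return a degenerate component
        warnings.warn("singular fit: sheep-intercept variance floored at 0")
        var_sheep = 0.0
    model = PgemModel(
        beta0=float(fe[0]),
        beta_time=float(fe[1]),
        beta_size={lev: float(fe[2 + i]) for i, lev in enumerate(_NONREF_LEVELS)},
        beta_interaction={lev: float(fe[6 + i]) for i, lev in enumerate(_NONREF_LEVELS)},
        sd_sheep=math.sqrt(var_sheep),
        sd_resid=math.sqrt(float(res.scale)),
    )
    return PgemFit(
        model=model,
        table=table,
        var_fixed=float(np.var(X @ fe)),
        loglik=float(res.llf),
        n_obs=len(y),
        n_sheep=int(records["sheep_id"].nunique()),
        converged=bool(res.converged),
    )


def nakagawa_r2(fit: PgemFit) -> tuple[float, float]:
    """Nakagawa marginal and conditional R² of a fitted PGEM model.

    marginal    = var_fixed / (var_fixed + var_sheep + var_resid)
    conditional = (var_fixed + var_sheep) / (same denominator)
    """
    var_sheep = (fit.model.sd_sheep or 0.0) ** 2
    var_resid = fit.model.sd_resid**2
    total = fit.var_fixed + var_sheep + var_resid
    if total <= 0:
        raise ValueError("total variance is zero; R^2 undefined")
    return fit.var_fixed / total, (fit.var_fixed + var_sheep) / total


def solve_variance_components(
    r2_marginal: float, r2_conditional: float, var_fixed: float
) -> tuple[float, float]:
    """Invert the Nakagawa R² definitions for the variance components.

    Given target marginal/conditional R² and the fixed-effect variance,
    returns ``(var_sheep, var_resid)`` such that :func:`nakagawa_r2`
    reproduces the targets exactly.
    """
    if not (0 < r2_marginal <= r2_conditional < 1):
        raise ValueError(
            f"require 0 < marginal <= conditional < 1, got ({r2_marginal}, {r2_conditional})"
        )
    if var_fixed <= 0:
        raise ValueError("var_fixed must be > 0")
    var_sheep = var_fixed * (r2_conditional - r2_marginal) / r2_marginal
    var_resid = var_fixed * (1.0 - r2_conditional) / r2_marginal
    return var_sheep, var_resid


def predict_pgem_curve(model: PgemModel, length_cm: int, times_h) -> np.ndarray:
    """Population-level predicted log10-PGEM over ``times_h`` for one cage size."""
    if length_cm not in CAGE_SIZE_LEVELS:
        raise ValueError(f"length_cm must be one of {CAGE_SIZE_LEVELS}, got {length_cm}")
    times_h = np.asarray(times_h, dtype=float)
    return model.linear_predictor(np.full(times_h.shape, length_cm), times_h)
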