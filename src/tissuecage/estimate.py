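"""Sequential nonlinear mixed-effects estimation for tissue-cage trials.

The fitting strategy mirrors how the sheep study was analysed: the
two-compartment plasma model is estimated first from plasma data alone;
each sheep's plasma kinetics are then condensed into empirical-Bayes
individual parameters; finally the cage transfer model (k13, k31 with
length / carrageenan / side covariates and per-cage lognormal random
effects) is estimated treating every sheep's fitted plasma curve as a
fixed forcing function.

Inference is maximum marginal likelihood with the random effects
integrated out by the Laplace approximation.  For each group (sheep for
the plasma stage, physical cage for the cage stage) the 2-dimensional
conditional mode of the random effects is located by a damped Newton
iteration, vectorised across all groups; the outer fixed-effect /
variance-component optimisation runs L-BFGS-B on log-transformed
positivity-constrained parameters.  Standard errors are Wald, from a
finite-difference Hessian of the marginal negative log-likelihood, with
delta-method back-transformation to the natural scale.  An adaptive
Gauss–Hermite integrator over the same conditional modes is provided as an
independent check of the Laplace approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .pk import CageParams, PlasmaParams

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "IndividualEstimates",
    "fit_plasma",
    "empirical_bayes",
    "individual_estimates",
    "fit_cages",
    "cage_empirical_bayes",
    "parameter_table",
    "agh_marginal_loglik",
]

_LOG2PI = math.log(2.0 * math.pi)
_Z95 = stats.norm.ppf(0.975)

# Optimiser settings (all overridable through fit_* keyword arguments).
# The outer FD step must stay well above the inner-solve noise floor, which
# the tight inner gradient tolerance keeps near machine precision.
DEFAULT_OUTER_OPTIONS = {"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-5}
INNER_GTOL = 1e-9
INNER_STEP_TOL = 1e-9
INNER_MAX_ITER = 100


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Param:
    name: str
    transform: str          # "log" or "id"
    init: float             # natural scale
    lower: float            # transformed scale
    upper: float            # transformed scale
    kind: str               # "fixed", "beta", "omega", "error"

    def to_x(self, value: float) -> float:
        return math.log(value) if self.transform == "log" else value

    def to_natural(self, x: float) -> float:
        return math.exp(x) if self.transform == "log" else x


def _unpack(spec: list[_Param], x: np.ndarray, dropped: dict[str, float]) -> dict[str, float]:
    out = dict(dropped)
    for p, xi in zip(spec, x):
        out[p.name] = p.to_natural(xi)
    return out


# ---------------------------------------------------------------------------
# Laplace machinery (2 random effects per group, vectorised across groups)
# ---------------------------------------------------------------------------

class _LaplaceProblem:
    """Grouped nonlinear model with 2 lognormal random effects per group.

    Subclasses provide :meth:`predict` plus the names of the omega and
    error-coefficient parameters; everything else (conditional-mode search,
    Laplace marginal likelihood, adaptive Gauss–Hermite cross-check) is
    generic.
    """

    n_eta = 2
    omega_names: tuple[str, str]
    b_name: str

    def __init__(self, y: np.ndarray, group_idx: np.ndarray, n_groups: int):
        self.y = np.asarray(y, dtype=float)
        self.g = np.asarray(group_idx, dtype=np.intp)
        self.G = int(n_groups)
        self.n_per_group = np.bincount(self.g, minlength=self.G).astype(float)

    def predict(self, params: dict[str, float], eta_obs: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- objective ---------------------------------------------------------

    def per_group_obj(self, params: dict[str, float], eta: np.ndarray) -> np.ndarray:
        """Joint negative log-density -log p(y_g | eta_g) - log p(eta_g), per group."""
        f = np.maximum(self.predict(params, eta[self.g]), 1e-10)
        b = max(params[self.b_name], 1e-12)
        sig = b * f
        dev = np.log(sig) + 0.5 * ((self.y - f) / sig) ** 2
        per_g = np.bincount(self.g, weights=dev, minlength=self.G)
        om = np.array([params[self.omega_names[0]], params[self.omega_names[1]]])
        om = np.maximum(om, 1e-12)
        prior = np.sum(np.log(om)) + 0.5 * np.sum((eta / om) ** 2, axis=1)
        return per_g + prior + 0.5 * _LOG2PI * (self.n_per_group + self.n_eta)

    def _fd_grad_hess(self, params, eta, h=1e-4):
        F = lambda e: self.per_group_obj(params, e)
        d1 = np.zeros_like(eta); d1[:, 0] = h
        d2 = np.zeros_like(eta); d2[:, 1] = h
        f0 = F(eta)
        fp1, fm1 = F(eta + d1), F(eta - d1)
        fp2, fm2 = F(eta + d2), F(eta - d2)
        fpp, fpm = F(eta + d1 + d2), F(eta + d1 - d2)
        fmp, fmm = F(eta - d1 + d2), F(eta - d1 - d2)
        grad = np.stack([(fp1 - fm1) / (2 * h), (fp2 - fm2) / (2 * h)], axis=1)
        h11 = (fp1 - 2 * f0 + fm1) / h**2
        h22 = (fp2 - 2 * f0 + fm2) / h**2
        h12 = (fpp - fpm - fmp + fmm) / (4 * h**2)
        hess = np.empty((self.G, 2, 2))
        hess[:, 0, 0] = h11; hess[:, 1, 1] = h22
        hess[:, 0, 1] = hess[:, 1, 0] = h12
        return f0, grad, hess

    def grad_hess(self, params, eta):
        """Objective, gradient and Hessian of the joint density per group.

        Default is a finite-difference stencil; subclasses may override
        with exact derivatives.
        """
        return self._fd_grad_hess(params, eta)

    def inner_solve(self, params, eta0=None, gtol=INNER_GTOL, max_iter=INNER_MAX_ITER):
        """Conditional modes of the random effects, damped Newton per group."""
        eta = np.zeros((self.G, 2)) if eta0 is None else eta0.copy()
        f0, grad, hess = self.grad_hess(params, eta)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < gtol:
                break
            # per-group 2x2 solve with positive-definiteness ridge
            with np.errstate(all="ignore"):
                a, bb, c = hess[:, 0, 0], hess[:, 0, 1], hess[:, 1, 1]
                tr, det = a + c, a * c - bb * bb
                lam_min = 0.5 * (tr - np.sqrt(np.maximum(tr * tr - 4 * det, 0.0)))
                ridge = np.maximum(1e-6, 1e-6 - lam_min) + np.where(
                    lam_min <= 0, -lam_min + 1e-3, 0.0
                )
                a_r, c_r = a + ridge, c + ridge
                det_r = a_r * c_r - bb * bb
                bad = ~np.isfinite(det_r) | (det_r <= 0)
                det_safe = np.where(bad, 1.0, det_r)
                step = np.stack(
                    [-(c_r * grad[:, 0] - bb * grad[:, 1]) / det_safe,
                     -(a_r * grad[:, 1] - bb * grad[:, 0]) / det_safe],
                    axis=1,
                )
                # ill-conditioned groups fall back to (clipped) steepest descent
                step = np.where(bad[:, None], -np.clip(grad, -1e6, 1e6), step)
                step = np.nan_to_num(step, nan=0.0, posinf=1e6, neginf=-1e6)
                norm = np.linalg.norm(step, axis=1)
                step *= np.minimum(1.0, 3.0 / np.maximum(norm, 1e-300))[:, None]
            # groups whose Newton step is below resolution are at a fixed
            # point: stop when all are, so repeated solves are bitwise stable
            if np.all(np.max(np.abs(step), axis=1) < INNER_STEP_TOL):
                break
            alpha = np.ones(self.G)
            cand, fc = eta, f0
            accept_tol = 1e-9 * (1.0 + np.abs(f0))
            for _bt in range(12):
                cand = eta + alpha[:, None] * step
                fc = self.per_group_obj(params, cand)
                improved = fc <= f0 + accept_tol
                if improved.all():
                    break
                alpha[~improved] *= 0.5
            improved = fc <= f0 + accept_tol
            eta = np.where(improved[:, None], cand, eta)
            f0, grad, hess = self.grad_hess(params, eta)
        return eta, f0, hess

    def laplace_nll(self, params, eta0=None):
        """Negative marginal log-likelihood under the Laplace approximation."""
        eta, f0, hess = self.inner_solve(params, eta0)
        det = np.maximum(hess[:, 0, 0] * hess[:, 1, 1] - hess[:, 0, 1] ** 2, 1e-12)
        nll = float(np.sum(f0) - 0.5 * self.G * self.n_eta * _LOG2PI + 0.5 * np.sum(np.log(det)))
        if not math.isfinite(nll):
            nll = 1e10  # reject this region; the line search will back off
        return nll, eta


def agh_marginal_loglik(problem: _LaplaceProblem, params: dict[str, float], n_nodes: int = 9) -> float:
    """Marginal log-likelihood by adaptive Gauss–Hermite quadrature.

    Nodes are centred at the Laplace conditional modes and scaled by the
    conditional curvature; with enough nodes this is an (almost) exact
    reference for the Laplace approximation on the same problem.
    """
    eta_hat, _, hess = problem.inner_solve(params)
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for gi in range(problem.G):
        H = hess[gi]
        cov = np.linalg.inv(H)
        A = np.linalg.cholesky(cov)
        logdetA = float(np.sum(np.log(np.diag(A))))
        terms = []
        for i in range(n_nodes):
            for j in range(n_nodes):
                u = np.array([z[i], z[j]])
                eta = eta_hat[gi] + math.sqrt(2.0) * (A @ u)
                e_all = eta_hat.copy()
                e_all[gi] = eta
                F = problem.per_group_obj(params, e_all)[gi]
                terms.append(math.log(w[i] * w[j]) - F + float(u @ u))
        total += (
            problem.n_eta / 2 * math.log(2.0)
            + logdetA
            + float(np.logaddexp.reduce(terms))
        )
    return total


# ---------------------------------------------------------------------------
# Stage 1: plasma model
# ---------------------------------------------------------------------------

def _two_compartment_conc(V, CL, k12, k21, dose, t):
    """Vectorised biexponential central concentration (array inputs)."""
    k10 = CL / V
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    c0 = dose / V
    a1 = c0 * (lam1 - k21) / disc
    a2 = c0 * (k21 - lam2) / disc
    return a1 * np.exp(-lam1 * t) + a2 * np.exp(-lam2 * t)


class _PlasmaProblem(_LaplaceProblem):
    """Plasma stage: per-sheep lognormal etas on V and CL."""

    omega_names = ("omega_V", "omega_CL")
    b_name = "b_plasma"

    def __init__(self, y, group_idx, n_groups, t, carr_sheep, dose):
        super().__init__(y, group_idx, n_groups)
        self.t = np.asarray(t, dtype=float)
        self.cs = np.asarray(carr_sheep, dtype=float)
        self.dose = float(dose)

    def predict(self, params, eta_obs):
        V = params["V"] * np.exp(eta_obs[:, 0])
        CL = params["CL"] * np.exp(eta_obs[:, 1])
        k12 = params["k12"] * np.exp(params["beta_k12_carr_sheep"] * self.cs)
        k21 = params["k21"] * np.exp(params["beta_k21_carr_sheep"] * self.cs)
        return _two_compartment_conc(V, CL, k12, k21, self.dose, self.t)

    def grad_hess(self, params, eta):
        """Exact per-group objective, gradient and Hessian in (eta1, eta2).

        eta1 scales V, eta2 scales CL.  Writing the biexponential as
        ``f = (dose/V) * H(k10)`` with ``H = d1*exp(-l1 t) + d2*exp(-l2 t)``
        and ``di = dli/dk10``, the eta-derivatives reduce to H' and H''
        in k10, which have closed forms through the root sensitivities.
        """
        e_obs = eta[self.g]
        V = params["V"] * np.exp(e_obs[:, 0])
        CL = params["CL"] * np.exp(e_obs[:, 1])
        k12 = params["k12"] * np.exp(params["beta_k12_carr_sheep"] * self.cs)
        k21 = params["k21"] * np.exp(params["beta_k21_carr_sheep"] * self.cs)
        t = self.t
        k10 = CL / V
        s = k10 + k12 + k21
        delta = np.sqrt(s * s - 4.0 * k10 * k21)
        l1 = 0.5 * (s + delta)
        l2 = 0.5 * (s - delta)
        d1 = (l1 - k21) / delta          # dl1/dk10, also the weight of e1
        d2 = (k21 - l2) / delta          # dl2/dk10, also the weight of e2
        e1 = np.exp(-l1 * t)
        e2 = np.exp(-l2 * t)
        P = self.dose / V
        H = d1 * e1 + d2 * e2
        c12 = 2.0 * d1 * d2 / delta      # dd1/dk10 = -dd2/dk10
        Hp = (c12 - t * d1 * d1) * e1 - (c12 + t * d2 * d2) * e2
        c12p = -6.0 * d1 * d2 * (d1 - d2) / delta**2
        Hpp = (
            (c12p - 4.0 * t * d1 * d1 * d2 / delta - t * d1 * c12 + t * t * d1**3) * e1
            + (-c12p + 4.0 * t * d1 * d2 * d2 / delta + t * d2 * c12 + t * t * d2**3) * e2
        )
        f = np.maximum(P * H, 1e-10)
        F1 = P * k10 * Hp
        F2 = P * k10 * k10 * Hpp
        dfa = -f - F1                    # df/deta1
        dfc = F1                         # df/deta2
        d2faa = f + 3.0 * F1 + F2
        d2fac = -2.0 * F1 - F2
        d2fcc = F1 + F2
        b = max(params[self.b_name], 1e-12)
        sig = b * f
        r = (self.y - f) / sig
        lp = 1.0 / f - r * self.y / (b * f * f)
        lpp = -1.0 / f**2 + (self.y / (b * f * f)) ** 2 + 2.0 * r * self.y / (b * f**3)
        dev = np.log(sig) + 0.5 * r * r
        om = np.maximum(
            np.array([params[self.omega_names[0]], params[self.omega_names[1]]]), 1e-12
        )
        f0 = (
            np.bincount(self.g, weights=dev, minlength=self.G)
            + np.sum(np.log(om))
            + 0.5 * np.sum((eta / om) ** 2, axis=1)
            + 0.5 * _LOG2PI * (self.n_per_group + self.n_eta)
        )
        g1 = np.bincount(self.g, weights=lp * dfa, minlength=self.G) + eta[:, 0] / om[0] ** 2
        g2 = np.bincount(self.g, weights=lp * dfc, minlength=self.G) + eta[:, 1] / om[1] ** 2
        h11 = (
            np.bincount(self.g, weights=lpp * dfa * dfa + lp * d2faa, minlength=self.G)
            + 1.0 / om[0] ** 2
        )
        h12 = np.bincount(self.g, weights=lpp * dfa * dfc + lp * d2fac, minlength=self.G)
        h22 = (
            np.bincount(self.g, weights=lpp * dfc * dfc + lp * d2fcc, minlength=self.G)
            + 1.0 / om[1] ** 2
        )
        grad = np.stack([g1, g2], axis=1)
        hess = np.empty((self.G, 2, 2))
        hess[:, 0, 0] = h11
        hess[:, 1, 1] = h22
        hess[:, 0, 1] = hess[:, 1, 0] = h12
        return f0, grad, hess


PLASMA_BETAS = ("beta_k12_carr_sheep", "beta_k21_carr_sheep")


def _plasma_initials(df: pd.DataFrame, dose: float) -> dict[str, float]:
    """Crude non-compartmental starting values from the pooled mean profile."""
    mean_prof = df.groupby("time_h")["conc_ug_ml"].mean().sort_index()
    t = mean_prof.index.to_numpy(dtype=float)
    c = np.maximum(mean_prof.to_numpy(dtype=float), 1e-9)
    v0 = dose / c[0]
    # terminal slope from the last three points of the mean profile
    tail = np.polyfit(t[-3:], np.log(c[-3:]), 1)
    lam_z = max(-tail[0], 1e-4)
    auc = np.trapezoid(c, t) + c[-1] / lam_z
    cl0 = dose / auc
    return {"V": v0, "CL": cl0, "k12": 0.1, "k21": 0.1}


def _prepare_plasma(records: pd.DataFrame) -> pd.DataFrame:
    df = records.loc[
        (records["matrix"] == "plasma")
        & (records["time_h"] > 0)
        & (~records["below_dose_time"].astype(bool))
    ].copy()
    if df["sheep_id"].nunique() < 2:
        raise ValueError("fit_plasma needs >= 2 sheep")
    per_sheep_times = df.groupby("sheep_id")["time_h"].nunique()
    if (per_sheep_times < 4).any():
        raise ValueError("fit_plasma needs >= 4 post-dose times per sheep")
    return df


@dataclass
class FitResult:
    """Estimates and Wald inference from one NLME stage (table-shaped)."""

    estimates: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    loglik: float
    converged: bool
    n_subjects: int
    n_obs: int
    message: str = ""
    fixed_zero: tuple[str, ...] = ()
    # internals kept for empirical-Bayes reuse
    _spec: list = field(default_factory=list, repr=False)
    _x: np.ndarray | None = field(default=None, repr=False)
    _dropped: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> dict[str, float]:
        """All natural-scale parameter values including dropped (zero) betas."""
        return {**self._dropped, **self.estimates}

    def table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "rse_percent": self.rse_percent.get(name, np.nan),
                    "ci_low": self.ci_low.get(name, np.nan),
                    "ci_high": self.ci_high.get(name, np.nan),
                    "p_value": self.p_values.get(name, np.nan),
                    "reference_zero": False,
                }
            )
        for name in self.fixed_zero:
            rows.append(
                {
                    "parameter": name,
                    "estimate": 0.0,
                    "rse_percent": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "reference_zero": True,
                }
            )
        return pd.DataFrame(rows)


def _pooled_prefit(problem, spec, dropped, x0, bounds):
    """Cheap naive-pooled pre-fit (random effects pinned at zero).

    Optimises the structural parameters, betas and error coefficient with
    eta = 0 — each evaluation is a single model prediction — to give the
    marginal-likelihood optimisation a good starting point.
    """
    idx = [i for i, p in enumerate(spec) if p.kind != "omega"]
    zero = np.zeros((problem.G, problem.n_eta))
    zero_obs = zero[problem.g]

    def fn(xsub):
        x = x0.copy()
        x[idx] = xsub
        params = _unpack(spec, x, dropped)
        f = np.maximum(problem.predict(params, zero_obs), 1e-10)
        sig = max(params[problem.b_name], 1e-12) * f
        return float(np.sum(np.log(sig) + 0.5 * ((problem.y - f) / sig) ** 2))

    res = minimize(
        fn, x0[idx], method="L-BFGS-B",
        bounds=[bounds[i] for i in idx],
        options={"maxiter": 300, "ftol": 1e-10},
    )
    x1 = x0.copy()
    x1[idx] = res.x
    return x1


def _run_fit(problem, spec, dropped, n_subjects, outer_options, compute_se, reference_rows):
    x0 = np.array([p.to_x(p.init) for p in spec])
    bounds = [(p.lower, p.upper) for p in spec]
    x0 = _pooled_prefit(problem, spec, dropped, x0, bounds)
    warm = {"eta": None, "best": np.inf}
    # per-observation scaling keeps the gradient O(1), so the identity
    # initial Hessian of L-BFGS-B yields sane first steps
    scale = 1.0 / max(1, len(problem.y))

    def nll_fn(x):
        nll, eta = problem.laplace_nll(_unpack(spec, x, dropped), warm["eta"])
        # keep warm-start modes only from sane regions, so a wild
        # line-search probe cannot poison later evaluations
        if nll < warm["best"] + 1e4:
            warm["eta"] = np.clip(eta, -15.0, 15.0)
            warm["best"] = min(warm["best"], nll)
        return nll * scale

    opts = dict(DEFAULT_OUTER_OPTIONS)
    if outer_options:
        opts.update(outer_options)
    res = minimize(nll_fn, x0, method="L-BFGS-B", bounds=bounds, options=opts)
    x_hat = res.x
    converged = bool(res.success)
    if not converged:
        logger.warning("outer optimisation did not converge: %s", res.message)

    estimates, se, rse, ci_lo, ci_hi, pvals = {}, {}, {}, {}, {}, {}
    for p, xi in zip(spec, x_hat):
        estimates[p.name] = p.to_natural(xi)
    se_ok = False
    if compute_se:
        H = _fd_hessian(nll_fn, x_hat)
        try:
            cov = np.linalg.inv(H) * scale  # undo the per-observation scaling
            d = np.sqrt(np.diag(cov))
            se_ok = np.all(np.isfinite(d)) and not np.any(np.diag(cov) < 0)
        except np.linalg.LinAlgError:
            se_ok = False
        if se_ok:
            for p, xi, si in zip(spec, x_hat, d):
                est = p.to_natural(xi)
                if p.transform == "log":
                    se[p.name] = abs(est) * si
                    ci_lo[p.name] = math.exp(xi - _Z95 * si)
                    ci_hi[p.name] = math.exp(xi + _Z95 * si)
                else:
                    se[p.name] = si
                    ci_lo[p.name] = xi - _Z95 * si
                    ci_hi[p.name] = xi + _Z95 * si
                    if p.kind == "beta":
                        pvals[p.name] = 2 * stats.norm.sf(abs(xi) / si) if si > 0 else np.nan
                rse[p.name] = 100.0 * se[p.name] / abs(est) if est != 0 else np.inf
        else:
            logger.warning("singular Hessian: standard errors unavailable")
    return FitResult(
        estimates=estimates,
        se=se,
        rse_percent=rse,
        ci_low=ci_lo,
        ci_high=ci_hi,
        p_values=pvals,
        loglik=-float(res.fun) / scale,
        converged=converged,
        n_subjects=n_subjects,
        n_obs=len(problem.y),
        message=str(res.message),
        fixed_zero=tuple(reference_rows),
        _spec=spec,
        _x=x_hat,
        _dropped=dropped,
    )


def _fd_hessian(fn, x, rel_step=5e-4):
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = fn(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpi, fmi = fn(x + ei), fn(x - ei)
        H[i, i] = (fpi - 2 * f0 + fmi) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fn(x + ei + ej)
            fpm = fn(x + ei - ej)
            fmp = fn(x - ei + ej)
            fmm = fn(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_plasma(
    records: pd.DataFrame,
    dose_mg_per_kg: float = 4.0,
    compute_se: bool = True,
    outer_options: dict | None = None,
) -> FitResult:
    """Population two-compartment fit to the plasma subset of a trial.

    Estimates {V, CL, k12, k21}, the carrageenan-in-sheep covariates on
    k12/k21 (dropped with a warning when the design does not vary the
    flag), the between-sheep SDs omega_V/omega_CL, and the proportional
    error coefficient b_plasma.
    """
    df = _prepare_plasma(records)
    sheep_ids = np.sort(df["sheep_id"].unique())
    g = pd.Categorical(df["sheep_id"], categories=sheep_ids).codes
    problem = _PlasmaProblem(
        df["conc_ug_ml"].to_numpy(),
        g,
        len(sheep_ids),
        df["time_h"].to_numpy(),
        df["carr_sheep"].to_numpy(dtype=float),
        dose_mg_per_kg,
    )
    init = _plasma_initials(df, dose_mg_per_kg)
    spec = [
        _Param("V", "log", init["V"], math.log(1e-4), math.log(1e2), "fixed"),
        _Param("CL", "log", init["CL"], math.log(1e-6), math.log(1e2), "fixed"),
        _Param("k12", "log", init["k12"], math.log(1e-5), math.log(1e3), "fixed"),
        _Param("k21", "log", init["k21"], math.log(1e-5), math.log(1e3), "fixed"),
    ]
    dropped: dict[str, float] = {}
    reference = ["beta_k12_no_carr_sheep", "beta_k21_no_carr_sheep"]
    if df["carr_sheep"].nunique() > 1:
        spec += [
            _Param("beta_k12_carr_sheep", "id", 0.0, -2.0, 2.0, "beta"),
            _Param("beta_k21_carr_sheep", "id", 0.0, -2.0, 2.0, "beta"),
        ]
    else:
        logger.warning("carr_sheep does not vary; dropping its covariate betas")
        dropped.update(beta_k12_carr_sheep=0.0, beta_k21_carr_sheep=0.0)
    spec += [
        _Param("omega_V", "log", 0.3, math.log(1e-6), math.log(10.0), "omega"),
        _Param("omega_CL", "log", 0.3, math.log(1e-6), math.log(10.0), "omega"),
        _Param("b_plasma", "log", 0.2, math.log(1e-4), math.log(10.0), "error"),
    ]
    return _run_fit(problem, spec, dropped, len(sheep_ids), outer_options, compute_se, reference)


# ---------------------------------------------------------------------------
# Empirical-Bayes individual plasma estimates
# ---------------------------------------------------------------------------

@dataclass
class IndividualEstimates:
    """Empirical-Bayes individual parameters from the sequential fit.

    ``plasma`` maps sheep id to reference-level :class:`PlasmaParams`
    (individual V and CL with the population k12/k21); the carrageenan
    multipliers reconstruct the period-specific k12/k21.  ``cages`` maps
    (sheep_id, side, length_cm) to the cage-level modes, filled by
    :func:`cage_empirical_bayes`.
    """

    plasma: dict[int, PlasmaParams]
    k12_carr_factor: float = 1.0
    k21_carr_factor: float = 1.0
    cages: dict[tuple, CageParams] = field(default_factory=dict)


def empirical_bayes(
    fit: FitResult, records: pd.DataFrame, dose_mg_per_kg: float = 4.0
) -> PlasmaParams:
    """Posterior-mode plasma parameters for a single sheep's records."""
    df = records.loc[
        (records["matrix"] == "plasma")
        & (records["time_h"] > 0)
        & (~records["below_dose_time"].astype(bool))
    ]
    sheep = df["sheep_id"].unique()
    if len(sheep) != 1:
        raise ValueError(f"empirical_bayes expects one sheep, got {sorted(sheep)}")
    params = fit.params
    problem = _PlasmaProblem(
        df["conc_ug_ml"].to_numpy(),
        np.zeros(len(df), dtype=int),
        1,
        df["time_h"].to_numpy(),
        df["carr_sheep"].to_numpy(dtype=float),
        dose_mg_per_kg,
    )
    try:
        eta, _, _ = problem.inner_solve(params)
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"empirical-Bayes step failed for sheep {sheep[0]}: {exc}") from exc
    return PlasmaParams(
        V=params["V"] * math.exp(eta[0, 0]),
        CL=params["CL"] * math.exp(eta[0, 1]),
        k12=params["k12"],
        k21=params["k21"],
    )


def individual_estimates(
    fit: FitResult, records: pd.DataFrame, dose_mg_per_kg: float = 4.0
) -> IndividualEstimates:
    """Empirical-Bayes plasma parameters for every sheep in the dataset."""
    params = fit.params
    plasma = {
        int(sheep): empirical_bayes(fit, grp, dose_mg_per_kg)
        for sheep, grp in records.loc[records["matrix"] == "plasma"].groupby("sheep_id")
    }
    return IndividualEstimates(
        plasma=plasma,
        k12_carr_factor=math.exp(params.get("beta_k12_carr_sheep", 0.0)),
        k21_carr_factor=math.exp(params.get("beta_k21_carr_sheep", 0.0)),
    )


# ---------------------------------------------------------------------------
# Stage 2: cage model conditional on individual plasma kinetics
# ---------------------------------------------------------------------------

def _phi(x):
    """(1 - exp(-x)) / x, arithmetic identical to _phi012's zeroth output.

    The objective used for the inner line search and the one differentiated
    by the Newton step must agree bitwise, so both go through this code path.
    """
    with np.errstate(all="ignore"):
        p0 = (1.0 - np.exp(-x)) / x
    m = np.abs(x) < 1e-3
    if m.any():
        xm = x[m]
        p0[m] = 1.0 - xm / 2.0 + xm * xm / 6.0
    return p0


def _phi012(x):
    """phi = (1 - exp(-x))/x and its first two derivatives, one shared exp.

    Small-|x| values switch to quadratic series expansions
    (phi(0), phi'(0), phi''(0)) = (1, -1/2, 1/3).
    """
    with np.errstate(all="ignore"):
        ex = np.exp(-x)
        x2 = x * x
        p0 = (1.0 - ex) / x
        p1 = (ex * (1.0 + x) - 1.0) / x2
        p2 = (2.0 - ex * (x2 + 2.0 * x + 2.0)) / (x * x2)
    m = np.abs(x) < 1e-3
    if m.any():
        xm = x[m]
        p0[m] = 1.0 - xm / 2.0 + xm * xm / 6.0
        p1[m] = -0.5 + xm / 3.0 - xm * xm / 8.0
        p2[m] = 1.0 / 3.0 - xm / 4.0 + xm * xm / 10.0
    return p0, p1, p2


class _CageProblem(_LaplaceProblem):
    """Cage stage: per-cage lognormal etas on k13 and k31; fixed forcing."""

    omega_names = ("omega_k13", "omega_k31")
    b_name = "b_cage"

    def __init__(self, y, group_idx, n_groups, t, length, carr_cage, side_right,
                 a1, a2, lam1, lam2):
        super().__init__(y, group_idx, n_groups)
        self.t = np.asarray(t, dtype=float)
        self.length = np.asarray(length, dtype=float)
        self.cc = np.asarray(carr_cage, dtype=float)
        self.sr = np.asarray(side_right, dtype=float)
        self.a1, self.a2 = np.asarray(a1), np.asarray(a2)
        self.lam1, self.lam2 = np.asarray(lam1), np.asarray(lam2)
        # parameter-independent pieces of the forcing kernel
        t2 = self.t * self.t
        b1 = self.a1 * np.exp(-self.lam1 * self.t)
        b2 = self.a2 * np.exp(-self.lam2 * self.t)
        self._bt1, self._bt2 = b1 * self.t, b2 * self.t
        self._btt1, self._btt2 = b1 * t2, b2 * t2
        self._bttt1, self._bttt2 = b1 * t2 * self.t, b2 * t2 * self.t

    def predict(self, params, eta_obs):
        k13, k31 = self._rates(params, eta_obs)
        return k13 * (
            self._bt1 * _phi((k31 - self.lam1) * self.t)
            + self._bt2 * _phi((k31 - self.lam2) * self.t)
        )

    def _rates(self, params, eta_obs):
        k13 = params["k13"] * np.exp(
            params["beta_k13_len"] * self.length
            + params["beta_k13_carr_cage"] * self.cc
            + params["beta_k13_side_right"] * self.sr
            + eta_obs[:, 0]
        )
        k31 = params["k31"] * np.exp(
            params["beta_k31_len"] * self.length
            + params["beta_k31_carr_cage"] * self.cc
            + params["beta_k31_side_right"] * self.sr
            + eta_obs[:, 1]
        )
        return k13, k31

    def grad_hess(self, params, eta):
        """Exact per-group objective, gradient and Hessian in (eta1, eta2).

        Uses that the cage prediction is ``f = k13 * S(k31)`` with
        ``k13 = base13 * exp(eta1)`` and ``k31 = base31 * exp(eta2)``, so
        ``df/deta1 = f`` and the eta2 derivatives reduce to derivatives of
        the stable exponential-difference kernel.
        """
        k13, k31 = self._rates(params, eta[self.g])
        b = max(params[self.b_name], 1e-12)
        t = self.t
        p0a, p1a, p2a = _phi012((k31 - self.lam1) * t)
        p0b, p1b, p2b = _phi012((k31 - self.lam2) * t)
        s = self._bt1 * p0a + self._bt2 * p0b
        s1 = self._btt1 * p1a + self._btt2 * p1b
        s2 = self._bttt1 * p2a + self._bttt2 * p2b
        f = np.maximum(k13 * s, 1e-10)
        df2 = k13 * k31 * s1                      # df/deta2
        d2f22 = k13 * (k31 * s1 + k31 * k31 * s2)  # d2f/deta2^2
        sig = b * f
        r = (self.y - f) / sig
        lp = 1.0 / f - r * self.y / (b * f * f)
        lpp = (
            -1.0 / f**2
            + (self.y / (b * f * f)) ** 2
            + 2.0 * r * self.y / (b * f**3)
        )
        dev = np.log(sig) + 0.5 * r * r
        om = np.maximum(
            np.array([params[self.omega_names[0]], params[self.omega_names[1]]]), 1e-12
        )
        f0 = (
            np.bincount(self.g, weights=dev, minlength=self.G)
            + np.sum(np.log(om))
            + 0.5 * np.sum((eta / om) ** 2, axis=1)
            + 0.5 * _LOG2PI * (self.n_per_group + self.n_eta)
        )
        g1 = np.bincount(self.g, weights=lp * f, minlength=self.G) + eta[:, 0] / om[0] ** 2
        g2 = np.bincount(self.g, weights=lp * df2, minlength=self.G) + eta[:, 1] / om[1] ** 2
        h11 = (
            np.bincount(self.g, weights=lpp * f * f + lp * f, minlength=self.G)
            + 1.0 / om[0] ** 2
        )
        h12 = np.bincount(self.g, weights=lpp * f * df2 + lp * df2, minlength=self.G)
        h22 = (
            np.bincount(self.g, weights=lpp * df2 * df2 + lp * d2f22, minlength=self.G)
            + 1.0 / om[1] ** 2
        )
        grad = np.stack([g1, g2], axis=1)
        hess = np.empty((self.G, 2, 2))
        hess[:, 0, 0] = h11
        hess[:, 1, 1] = h22
        hess[:, 0, 1] = hess[:, 1, 0] = h12
        return f0, grad, hess


CAGE_BETAS = (
    "beta_k13_len", "beta_k13_carr_cage", "beta_k13_side_right",
    "beta_k31_len", "beta_k31_carr_cage", "beta_k31_side_right",
)


def _cage_forcing(df: pd.DataFrame, individuals: IndividualEstimates, dose: float):
    """Per-observation macro constants of each sheep-period plasma curve."""
    a1 = np.empty(len(df)); a2 = np.empty(len(df))
    l1 = np.empty(len(df)); l2 = np.empty(len(df))
    for (sheep, carr), idx in df.groupby(["sheep_id", "carr_sheep"]).groups.items():
        if int(sheep) not in individuals.plasma:
            raise ValueError(f"no individual plasma estimates for sheep {sheep}")
        base = individuals.plasma[int(sheep)]
        k12 = base.k12 * (individuals.k12_carr_factor if carr else 1.0)
        k21 = base.k21 * (individuals.k21_carr_factor if carr else 1.0)
        k10 = base.CL / base.V
        s = k10 + k12 + k21
        disc = math.sqrt(s * s - 4 * k10 * k21)
        lam1, lam2 = 0.5 * (s + disc), 0.5 * (s - disc)
        c0 = dose / base.V
        loc = df.index.get_indexer(idx)
        a1[loc] = c0 * (lam1 - k21) / disc
        a2[loc] = c0 * (k21 - lam2) / disc
        l1[loc] = lam1
        l2[loc] = lam2
    return a1, a2, l1, l2


def fit_cages(
    records: pd.DataFrame,
    individuals: IndividualEstimates,
    dose_mg_per_kg: float = 4.0,
    compute_se: bool = True,
    outer_options: dict | None = None,
) -> FitResult:
    """Cage-stage fit conditional on each sheep's fitted plasma curve.

    Estimates the typical k13/k31 at reference covariates, log-linear
    covariates for cage length (per cm), carrageenan-in-cage and right
    side, the between-cage SDs, and the cage proportional error.  Betas
    whose covariate does not vary in the data are dropped with a warning.
    """
    df = records.loc[
        (records["matrix"] == "cage")
        & (records["time_h"] > 0)
        & (~records["below_dose_time"].astype(bool))
    ].copy()
    if df.empty:
        raise ValueError("no post-dose cage records")
    cage_key = list(zip(df["sheep_id"], df["side"], df["length_cm"]))
    keys = sorted(set(cage_key), key=str)
    g = pd.Categorical(pd.Series(cage_key).astype(str), categories=[str(k) for k in keys]).codes
    a1, a2, l1, l2 = _cage_forcing(df, individuals, dose_mg_per_kg)
    problem = _CageProblem(
        df["conc_ug_ml"].to_numpy(), g, len(keys),
        df["time_h"].to_numpy(), df["length_cm"].to_numpy(),
        df["carr_cage"].to_numpy(dtype=float),
        (df["side"] == "right").to_numpy(dtype=float),
        a1, a2, l1, l2,
    )
    spec = [
        _Param("k13", "log", 0.1, math.log(1e-5), math.log(1e2), "fixed"),
        _Param("k31", "log", 0.2, math.log(1e-5), math.log(1e2), "fixed"),
    ]
    dropped: dict[str, float] = {}
    reference = [
        "beta_k13_no_carr_cage", "beta_k31_no_carr_cage",
        "beta_k13_side_left", "beta_k31_side_left",
    ]
    covariate_cols = {
        "beta_k13_len": df["length_cm"], "beta_k31_len": df["length_cm"],
        "beta_k13_carr_cage": df["carr_cage"], "beta_k31_carr_cage": df["carr_cage"],
        "beta_k13_side_right": df["side"], "beta_k31_side_right": df["side"],
    }
    for name in CAGE_BETAS:
        if covariate_cols[name].nunique() > 1:
            spec.append(_Param(name, "id", 0.0, -2.0, 2.0, "beta"))
        else:
            logger.warning("covariate for %s does not vary; beta dropped", name)
            dropped[name] = 0.0
    spec += [
        _Param("omega_k13", "log", 0.3, math.log(1e-6), math.log(10.0), "omega"),
        _Param("omega_k31", "log", 0.3, math.log(1e-6), math.log(10.0), "omega"),
        _Param("b_cage", "log", 0.3, math.log(1e-4), math.log(10.0), "error"),
    ]
    fit = _run_fit(problem, spec, dropped, df["sheep_id"].nunique(),
                   outer_options, compute_se, reference)
    fit._cage_keys = keys  # attached for the cage EB step
    return fit


def cage_empirical_bayes(
    cage_fit: FitResult,
    records: pd.DataFrame,
    individuals: IndividualEstimates,
    dose_mg_per_kg: float = 4.0,
) -> IndividualEstimates:
    """Fill per-cage empirical-Bayes k13/k31 modes into ``individuals``.

    The returned CageParams are the individual rate constants at each
    cage's own covariates (length, side, carrageenan state averaged is not
    meaningful, so the non-inflamed context is reported: covariates length
    and side applied, carrageenan at reference).
    """
    df = records.loc[
        (records["matrix"] == "cage")
        & (records["time_h"] > 0)
        & (~records["below_dose_time"].astype(bool))
    ].copy()
    params = cage_fit.params
    for key, grp in df.groupby(["sheep_id", "side", "length_cm"]):
        a1, a2, l1, l2 = _cage_forcing(grp, individuals, dose_mg_per_kg)
        problem = _CageProblem(
            grp["conc_ug_ml"].to_numpy(), np.zeros(len(grp), dtype=int), 1,
            grp["time_h"].to_numpy(), grp["length_cm"].to_numpy(),
            grp["carr_cage"].to_numpy(dtype=float),
            (grp["side"] == "right").to_numpy(dtype=float),
            a1, a2, l1, l2,
        )
        eta, _, _ = problem.inner_solve(params)
        sheep, side, length = key
        k13 = params["k13"] * math.exp(
            params["beta_k13_len"] * length
            + params["beta_k13_side_right"] * (side == "right")
            + eta[0, 0]
        )
        k31 = params["k31"] * math.exp(
            params["beta_k31_len"] * length
            + params["beta_k31_side_right"] * (side == "right")
            + eta[0, 1]
        )
        individuals.cages[(int(sheep), str(side), float(length))] = CageParams(k13=k13, k31=k31)
    return individuals


def parameter_table(plasma_fit: FitResult, cage_fit: FitResult) -> pd.DataFrame:
    """Merged population-parameter report from both stages.

    One row per estimated fixed effect, covariate beta, random-effect SD
    and error coefficient, with reference levels shown as fixed zeros.
    """
    if not (plasma_fit.converged and cage_fit.converged):
        raise ValueError("parameter_table requires converged fits")
    t1 = plasma_fit.table(); t1.insert(0, "stage", "plasma")
    t2 = cage_fit.table(); t2.insert(0, "stage", "cage")
    return pd.concat([t1, t2], ignore_index=True)
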