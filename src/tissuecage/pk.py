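"""Closed-form kinetics of the tissue-cage pharmacokinetic model.

Plasma disposition after an intravenous bolus is a linear two-compartment
model (central volume V, clearance CL, inter-compartment rates k12/k21).  A
tissue cage is appended as a *forcing-function* compartment: its
concentration obeys

    dC3/dt = k13 * C1(t) - k31 * C3,   C3(0) = 0,

where C1(t) is the central-compartment concentration.  Because only a
negligible fraction of drug ever enters the cage, the cage does not feed
back on plasma — the plasma model is solved first and acts as a known
forcing function.  All solutions here are exact closed forms; a stiff ODE
integrator is used only as an independent oracle in the test-suite.

Units: dose in mg/kg, volumes in L/kg, clearance in L/(h·kg), rates in h⁻¹;
concentrations come out in µg/mL (mg/L).

Covariates (cage length, carrageenan flags, cage side) act log-linearly on
the rate constants: ``k = k_pop * exp(sum(beta_i * x_i))`` with the
reference level (left side, no carrageenan, length entering uncentered in
cm) contributing zero.  Between-subject and between-cage variability is
lognormal: individual parameters are the covariate-adjusted typical values
times ``exp(eta)``, ``eta ~ Normal(0, omega^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PlasmaParams",
    "CageParams",
    "CovariateEffects",
    "RandomEffectSDs",
    "ErrorModel",
    "PopulationModel",
    "MacroConstants",
    "reference_model",
    "macro_constants",
    "plasma_conc",
    "cage_conc",
    "cage_tmax",
    "half_life_from_rate",
    "terminal_half_life",
    "apply_covariates",
    "draw_individual",
    "fick_rate",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlasmaParams:
    """Two-compartment IV-bolus disposition parameters (per-kg basis)."""

    V: float      # central volume, L/kg
    CL: float     # clearance, L/(h·kg)
    k12: float    # central -> peripheral, h^-1
    k21: float    # peripheral -> central, h^-1

    def __post_init__(self) -> None:
        for name in ("V", "CL", "k12", "k21"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PlasmaParams.{name} must be > 0")

    @property
    def k10(self) -> float:
        """Elimination rate constant CL/V, h⁻¹."""
        return self.CL / self.V


@dataclass(frozen=True)
class CageParams:
    """Cage transfer rate constants (typical values at reference covariates)."""

    k13: float    # central -> cage, h^-1
    k31: float    # cage -> central, h^-1

    def __post_init__(self) -> None:
        if self.k13 <= 0 or self.k31 <= 0:
            raise ValueError("CageParams rates must be > 0")


@dataclass(frozen=True)
class CovariateEffects:
    """Log-scale covariate coefficients on the rate constants.

    Reference level: left side, no carrageenan in cage, no carrageenan in
    the animal; cage length enters uncentered in cm.
    """

    beta_k12_carr_sheep: float = 0.0
    beta_k21_carr_sheep: float = 0.0
    beta_k31_len: float = 0.0
    beta_k13_len: float = 0.0
    beta_k31_carr_cage: float = 0.0
    beta_k13_carr_cage: float = 0.0
    beta_k31_side_right: float = 0.0
    beta_k13_side_right: float = 0.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise ValueError(f"CovariateEffects.{name} must be finite")


@dataclass(frozen=True)
class RandomEffectSDs:
    """SDs of the log-scale random effects (lognormal variability)."""

    omega_V: float = 0.0       # between-sheep
    omega_CL: float = 0.0      # between-sheep
    omega_k31: float = 0.0     # between-cage
    omega_k13: float = 0.0     # between-cage

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"RandomEffectSDs.{name} must be >= 0")


@dataclass(frozen=True)
class ErrorModel:
    """Proportional residual error: y = f * (1 + b * eps), eps ~ N(0, 1)."""

    b_plasma: float = 0.0
    b_cage: float = 0.0

    def __post_init__(self) -> None:
        if self.b_plasma < 0 or self.b_cage < 0:
            raise ValueError("error coefficients must be >= 0")


@dataclass(frozen=True)
class PopulationModel:
    """Full population PK model: typical values, covariates, variability."""

    plasma: PlasmaParams
    cage: CageParams
    covariates: CovariateEffects = field(default_factory=CovariateEffects)
    omegas: RandomEffectSDs = field(default_factory=RandomEffectSDs)
    error: ErrorModel = field(default_factory=ErrorModel)
    dose_mg_per_kg: float = 4.0

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg <= 0:
            raise ValueError("dose_mg_per_kg must be > 0")


def reference_model() -> PopulationModel:
    """Population model for 4 mg/kg IV carprofen in sheep with neck tissue
    cages (the published population estimates this package was built
    around).  Used as the default generating model for simulated trials."""
    return PopulationModel(
        plasma=PlasmaParams(V=0.0924, CL=0.00235, k12=0.121, k21=0.200),
        cage=CageParams(k13=0.124, k31=0.455),
        covariates=CovariateEffects(
            beta_k12_carr_sheep=0.00114,
            beta_k21_carr_sheep=0.336,
            beta_k31_len=-0.147,
            beta_k13_len=-0.0378,
            beta_k31_carr_cage=-0.104,
            beta_k13_carr_cage=-0.184,
            beta_k31_side_right=-0.0701,
            beta_k13_side_right=-0.024,
        ),
        omegas=RandomEffectSDs(
            omega_V=0.188, omega_CL=0.448, omega_k31=0.522, omega_k13=0.482
        ),
        error=ErrorModel(b_plasma=0.136, b_cage=0.468),
        dose_mg_per_kg=4.0,
    )


@dataclass(frozen=True)
class MacroConstants:
    """Macro (sum-of-exponentials) form of the two-compartment solution.

    C1(t) = coef_fast * exp(-lambda_fast * t) + coef_slow * exp(-lambda_slow * t)
    """

    lambda_fast: float
    lambda_slow: float
    coef_fast: float
    coef_slow: float

    def __post_init__(self) -> None:
        if not (self.lambda_fast > self.lambda_slow > 0):
            raise ValueError("require lambda_fast > lambda_slow > 0")


# ---------------------------------------------------------------------------
# Closed-form solutions
# ---------------------------------------------------------------------------

def macro_constants(p: PlasmaParams, dose_mg_per_kg: float) -> MacroConstants:
    """Disposition exponents and coefficients of the two-compartment model.

    The exponents are the roots of ``l^2 - (k10+k12+k21) l + k10*k21 = 0``
    (eigenvalues of the 2x2 first-order rate matrix); the coefficients
    satisfy ``coef_fast + coef_slow = dose / V``.
    """
    k10 = p.k10
    s = k10 + p.k12 + p.k21
    prod = k10 * p.k21
    disc = s * s - 4.0 * prod
    # for positive rates disc = (k10+k12-k21)^2 + 4 k12 k21 > 0 always
    assert disc > 0, "characteristic discriminant must be positive"
    root = math.sqrt(disc)
    lam_fast = 0.5 * (s + root)
    lam_slow = 0.5 * (s - root)
    c0 = dose_mg_per_kg / p.V
    coef_fast = c0 * (lam_fast - p.k21) / (lam_fast - lam_slow)
    coef_slow = c0 * (p.k21 - lam_slow) / (lam_fast - lam_slow)
    return MacroConstants(lam_fast, lam_slow, coef_fast, coef_slow)


def plasma_conc(p: PlasmaParams, dose_mg_per_kg: float, t):
    """Central-compartment concentration (µg/mL) at time(s) ``t`` (h).

    Biexponential closed form; linear in dose.  ``t`` may be a scalar or an
    array; negative times raise (pre-dose samples are the caller's concern).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("plasma_conc requires t >= 0")
    m = macro_constants(p, dose_mg_per_kg)
    out = m.coef_fast * np.exp(-m.lambda_fast * t_arr) + m.coef_slow * np.exp(
        -m.lambda_slow * t_arr
    )
    return out if out.ndim else float(out)


def _phi(x):
    """Stable (1 - exp(-x)) / x with phi(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0, -np.expm1(-safe) / safe)
    return out


def cage_conc(p: PlasmaParams, c: CageParams, dose_mg_per_kg: float, t):
    """Cage-compartment concentration (µg/mL) at time(s) ``t`` (h).

    Exact solution of ``dC3/dt = k13*C1(t) - k31*C3`` with ``C3(0)=0``:

        C3(t) = k13 * sum_i coef_i * (exp(-lambda_i t) - exp(-k31 t)) / (k31 - lambda_i)

    evaluated through the numerically stable kernel
    ``t*exp(-lambda t)*phi((k31-lambda) t)``, which has the correct
    ``t*exp(-lambda t)`` limit when ``k31`` is (near-)degenerate with a
    disposition exponent.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("cage_conc requires t >= 0")
    m = macro_constants(p, dose_mg_per_kg)
    out = np.zeros_like(t_arr)
    for lam, coef in ((m.lambda_fast, m.coef_fast), (m.lambda_slow, m.coef_slow)):
        out = out + coef * t_arr * np.exp(-lam * t_arr) * _phi((c.k31 - lam) * t_arr)
    out = c.k13 * out
    return out if out.ndim else float(out)


def cage_tmax(
    p: PlasmaParams, c: CageParams, dose_mg_per_kg: float, t_upper: float = 2000.0
) -> float:
    """Time (h) of the cage-concentration maximum.

    The maximum is the unique positive root of
    ``dC3/dt = k13*C1(t) - k31*C3(t)``; the derivative is positive at 0+
    (the cage starts empty) and negative for large t, so the root is
    bracketed by doubling and solved with Brent's method.
    """
    def deriv(t: float) -> float:
        return c.k13 * plasma_conc(p, dose_mg_per_kg, t) - c.k31 * cage_conc(
            p, c, dose_mg_per_kg, t
        )

    lo, hi = 1e-8, 1.0
    while deriv(hi) > 0:
        lo = hi
        hi *= 2.0
        if hi > t_upper:
            raise RuntimeError(
                f"cage_tmax: no sign change of dC3/dt up to t={t_upper} h "
                f"(k13={c.k13}, k31={c.k31})"
            )
    return float(brentq(deriv, lo, hi, xtol=1e-10, rtol=1e-12))


def half_life_from_rate(k: float) -> float:
    """Half-life ln(2)/k (h) of a first-order rate constant k (h⁻¹)."""
    if k <= 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    return math.log(2.0) / k


def terminal_half_life(p: PlasmaParams) -> float:
    """Terminal plasma half-life ln(2)/lambda_slow (h)."""
    m = macro_constants(p, dose_mg_per_kg=1.0)  # exponents are dose-free
    return math.log(2.0) / m.lambda_slow


def fick_rate(permeability_cm_per_h: float, sav_per_cm: float) -> float:
    """First-order transfer rate from Fick's law: k = permeability * SA/V.

    Under Fick's law the flux into a well-stirred cage is proportional to the
    diffusible area times the concentration gradient; dividing by the cage
    volume gives a rate constant proportional to SA/V.  Cages with equal
    SA/V therefore share rate constants regardless of absolute size.
    """
    if permeability_cm_per_h < 0 or sav_per_cm < 0:
        raise ValueError("permeability and SA/V must be >= 0")
    return permeability_cm_per_h * sav_per_cm


# ---------------------------------------------------------------------------
# Covariates and individual draws
# ---------------------------------------------------------------------------

def apply_covariates(
    m: PopulationModel,
    length_cm: float,
    carr_cage: bool,
    carr_sheep: bool,
    side_right: bool,
) -> tuple[PlasmaParams, CageParams]:
    """Covariate-adjusted typical parameter values for one cage context.

    Each rate constant is ``pop_value * exp(sum(beta * covariate))`` with
    length in cm uncentered and flags in {0, 1}; V and CL carry no
    covariates.
    """
    if length_cm < 0:
        raise ValueError("length_cm must be >= 0")
    cov = m.covariates
    cs = 1.0 if carr_sheep else 0.0
    cc = 1.0 if carr_cage else 0.0
    sr = 1.0 if side_right else 0.0
    plasma = replace(
        m.plasma,
        k12=m.plasma.k12 * math.exp(cov.beta_k12_carr_sheep * cs),
        k21=m.plasma.k21 * math.exp(cov.beta_k21_carr_sheep * cs),
    )
    cage = CageParams(
        k13=m.cage.k13
        * math.exp(
            cov.beta_k13_len * length_cm
            + cov.beta_k13_carr_cage * cc
            + cov.beta_k13_side_right * sr
        ),
        k31=m.cage.k31
        * math.exp(
            cov.beta_k31_len * length_cm
            + cov.beta_k31_carr_cage * cc
            + cov.beta_k31_side_right * sr
        ),
    )
    return plasma, cage


def draw_individual(
    m: PopulationModel,
    length_cm: float,
    carr_cage: bool,
    carr_sheep: bool,
    side_right: bool,
    rng: np.random.Generator | int,
    sheep_eta: np.ndarray | None = None,
    cage_eta: np.ndarray | None = None,
) -> tuple[PlasmaParams, CageParams]:
    """Draw individual parameters: typical values times exp(eta).

    V and CL share one per-sheep pair of etas; k13 and k31 get an
    independent per-cage pair; k12 and k21 carry no random effects.  Etas
    may be supplied (so the same sheep/cage can be reused across contexts)
    or drawn from ``rng``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sheep_eta is None:
        sheep_eta = rng.normal(size=2) * [m.omegas.omega_V, m.omegas.omega_CL]
    if cage_eta is None:
        cage_eta = rng.normal(size=2) * [m.omegas.omega_k13, m.omegas.omega_k31]
    plasma_typ, cage_typ = apply_covariates(
        m, length_cm, carr_cage, carr_sheep, side_right
    )
    plasma = replace(
        plasma_typ,
        V=plasma_typ.V * math.exp(sheep_eta[0]),
        CL=plasma_typ.CL * math.exp(sheep_eta[1]),
    )
    cage = CageParams(
        k13=cage_typ.k13 * math.exp(cage_eta[0]),
        k31=cage_typ.k31 * math.exp(cage_eta[1]),
    )
    return plasma, cage
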