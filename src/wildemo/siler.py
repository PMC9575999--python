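"""Siler mortality hazard, covariate modifiers, and longevity functionals.

The Siler model expresses age-specific mortality hazard as the sum of three
components: a declining immature hazard, a constant baseline, and an
exponentially increasing senescent hazard,

    h(a) = a1 * exp(-b1 * a) + a2 + a3 * exp(b3 * a).

Covariates act multiplicatively on the hazard through exponentiated linear
terms (a proportional-hazards form): a wet-season increment ``beta_s``, a
slope ``beta_l`` per km of distance along the migratory axis, and per-year
increments ``beta_y`` constrained to sum to zero across study years so the
baseline remains interpretable as the across-year mean.

Survivorship has the closed form S(a) = exp(-H(a)) with

    H(a) = a1/b1 * (1 - exp(-b1*a)) + a2*a + a3/b3 * (exp(b3*a) - 1),

where the b1 -> 0 and b3 -> 0 limits reduce the corresponding terms to
``a1*a`` and ``a3*a``.  Longevity is defined as the age reached by a stated
fraction of females (default 0.1%), life expectancy as the integral of
survivorship (no closed-form antiderivative exists, so it is computed by
adaptive quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "SilerParams",
    "HazardModifiers",
    "CovariateInterval",
    "siler_hazard",
    "siler_cumulative_hazard",
    "siler_survivorship",
    "modified_hazard",
    "cumulative_hazard_piecewise",
    "longevity",
    "life_expectancy",
]

_B_TINY = 1e-12


@dataclass(frozen=True)
class SilerParams:
    """The five baseline Siler hazard parameters (all units 1/yr except the
    dimensionless-in-effect rates b1, b3 which are 1/yr decay/growth rates).

    a1 : immature hazard scale
    b1 : immature hazard decay rate
    a2 : constant (age-independent) hazard
    a3 : senescent hazard scale
    b3 : senescent hazard growth rate
    """

    a1: float
    b1: float
    a2: float
    a3: float
    b3: float

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "a3", "b3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"SilerParams.{name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {"a1": self.a1, "b1": self.b1, "a2": self.a2,
                "a3": self.a3, "b3": self.b3}


@dataclass(frozen=True)
class HazardModifiers:
    """Log-hazard covariate effects.

    beta_s  : wet-season log-hazard increment (dimensionless)
    beta_l  : log-hazard slope per km along the migratory axis (1/km);
              negative values mean higher hazard toward the southeastern
              (low-distance) end of the corridor
    beta_y  : mapping calendar year -> log-hazard increment; by convention
              constrained to sum to zero across study years
    gamma_d : slope of the calf-dissociation hazard with age beyond 0.75 yr
              (1/yr per yr); must be >= 0
    strict_years : if True, a year absent from ``beta_y`` is an error;
              otherwise it is treated as the reference (zero effect)
    """

    beta_s: float = 0.0
    beta_l: float = 0.0
    beta_y: Mapping[int, float] = field(default_factory=dict)
    gamma_d: float = 0.0
    strict_years: bool = False

    def __post_init__(self) -> None:
        if self.gamma_d < 0:
            raise ValueError(f"gamma_d must be >= 0, got {self.gamma_d}")

    def year_effect(self, year: int) -> float:
        if year in self.beta_y:
            return self.beta_y[year]
        if self.strict_years:
            raise KeyError(f"no year effect defined for {year}")
        return 0.0

    def log_modifier(self, season: str, location_km: float, year: int) -> float:
        """Linear predictor beta_s*[wet] + beta_l*x + beta_y[year]."""
        if season not in ("wet", "dry"):
            raise ValueError(f"season must be 'wet' or 'dry', got {season!r}")
        return (self.beta_s * (season == "wet")
                + self.beta_l * location_km
                + self.year_effect(year))


def siler_hazard(params: SilerParams, age):
    """Baseline Siler hazard h(a) (1/yr); vectorized over ``age``."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    h = (params.a1 * np.exp(-params.b1 * age)
         + params.a2
         + params.a3 * np.exp(params.b3 * age))
    return h if h.ndim else float(h)


def siler_cumulative_hazard(params: SilerParams, age):
    """Closed-form cumulative hazard H(a); vectorized over ``age``.

    The degenerate rates b1 = 0 / b3 = 0 are handled by their series limits
    (a1*a and a3*a), keeping the function continuous for sampler moves near
    zero.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    with np.errstate(over="ignore"):  # huge b3*age -> inf is a valid limit
        if params.a1 == 0:
            imm = 0.0
        elif params.b1 > _B_TINY:
            imm = params.a1 / params.b1 * (-np.expm1(-params.b1 * age))
        else:
            imm = params.a1 * age
        if params.a3 == 0:
            sen = 0.0
        elif params.b3 > _B_TINY:
            sen = params.a3 / params.b3 * np.expm1(params.b3 * age)
        else:
            sen = params.a3 * age
        H = imm + params.a2 * age + sen
    return H if H.ndim else float(H)


def siler_survivorship(params: SilerParams, age):
    """Survivorship S(a) = exp(-H(a)), in (0, 1]; nonincreasing in age."""
    return np.exp(-np.asarray(siler_cumulative_hazard(params, age))) \
        if np.ndim(age) else float(np.exp(-siler_cumulative_hazard(params, age)))


def modified_hazard(params: SilerParams, mods: HazardModifiers, age,
                    season: str, location_km: float, year: int):
    """Covariate-modified hazard h(a) * exp(beta_s*[wet] + beta_l*x + beta_y[y])."""
    return siler_hazard(params, age) * float(
        np.exp(mods.log_modifier(season, location_km, year)))


@dataclass(frozen=True)
class CovariateInterval:
    """One piece of a piecewise-constant covariate path over an age span."""

    age_start: float
    age_end: float
    season: str
    location_km: float
    year: int


def cumulative_hazard_piecewise(
    params: SilerParams,
    mods: HazardModifiers,
    age_start: float,
    age_end: float,
    path: Sequence[CovariateInterval],
    *,
    rtol: float = 1e-9,
) -> float:
    """Integrated modified hazard over [age_start, age_end] along a covariate
    path whose intervals must exactly partition the span.

    Within each interval the modifier is constant, so the contribution is
    exp(linear predictor) * [H(end) - H(start)] and the total is additive
    over adjacent intervals.
    """
    if age_end < age_start:
        raise ValueError("age_end < age_start")
    if not path:
        if age_end > age_start:
            raise ValueError("empty covariate path over a nonempty age span")
        return 0.0
    ivs = sorted(path, key=lambda iv: iv.age_start)
    tol = rtol * max(1.0, abs(age_end))
    if abs(ivs[0].age_start - age_start) > tol or abs(ivs[-1].age_end - age_end) > tol:
        raise ValueError("covariate path does not span [age_start, age_end]")
    total = 0.0
    for prev, cur in zip(ivs, ivs[1:]):
        if abs(prev.age_end - cur.age_start) > tol:
            raise ValueError(
                f"covariate path has a gap or overlap at age {prev.age_end:g}/{cur.age_start:g}")
    H = siler_cumulative_hazard
    for iv in ivs:
        mult = np.exp(mods.log_modifier(iv.season, iv.location_km, iv.year))
        total += mult * (H(params, iv.age_end) - H(params, iv.age_start))
    return float(total)


def longevity(params: SilerParams, survivorship_quantile: float = 0.001,
              *, max_age: float = 100.0, xtol: float = 1e-6) -> float:
    """Age reached by the stated fraction of females (default 0.1%).

    Solves S(a) = q by bracketed root finding on the cumulative hazard.
    """
    q = survivorship_quantile
    if not 0.0 < q < 1.0:
        raise ValueError("survivorship_quantile must be in (0, 1)")
    target = -np.log(q)
    if siler_cumulative_hazard(params, max_age) < target:
        raise ValueError(
            f"survivorship never reaches {q:g} within {max_age:g} yr")
    return float(brentq(
        lambda a: siler_cumulative_hazard(params, a) - target,
        0.0, max_age, xtol=xtol))


def life_expectancy(params: SilerParams, *, tail_survivorship: float = 1e-12) -> float:
    """Life expectancy at birth: the integral of survivorship.

    There is no closed-form antiderivative of the Siler survivorship, so the
    integral is computed by adaptive quadrature up to the age where
    survivorship falls below ``tail_survivorship`` (the neglected tail is
    below that bound in years).
    """
    if params.a1 == 0 and params.a2 == 0 and params.a3 == 0:
        raise ValueError("all-zero hazard: life expectancy diverges")
    try:
        upper = longevity(params, tail_survivorship, max_age=10_000.0)
    except ValueError as exc:  # hazard vanishes asymptotically
        raise ValueError("survivorship integral does not converge") from exc
    val, _err = quad(lambda a: np.exp(-siler_cumulative_hazard(params, a)),
                     0.0, upper, epsrel=1e-10, epsabs=1e-12, limit=500)
    return float(val)
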