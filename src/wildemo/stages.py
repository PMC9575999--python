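"""Staged model fits with sequential posterior-to-prior chaining.

The full survival/recruitment model is fitted as a sequence of stages, each
pairing one dataset with one parameter subset:

    CC    collared-cow survival, adult Siler parameters (a2, a3, b3)
    CC.S  + wet-season effect beta_s
    CC.L  + location effect beta_l (per km along the migratory axis)
    CC.Y  + per-year effects beta_y (sum-to-zero across study years)
    HC    herd counts: fecundity f + the calf-relevant hazard parameters
    HC.Y  per-calf-year fecundity and year effects
    CD    calf detections: f, detection p, false-detection q, dissociation
    CD.Y  per-calf-year fecundity from detections

After each stage the pooled posterior of every sampled parameter is
moment-matched by an independent normal on its transformed scale, and that
normal becomes the prior whenever a later stage samples the same parameter.
Parameters never seen before receive the weak default prior normal(0, 10)
on the transformed scale.  The effect stages (S, L, Y) are separate
single-effect extensions of the base stage, not one joint model.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import PosteriorChains, metropolis_sample
from .likelihoods import (cc_loglik, cd_loglik, compile_calf_data,
                          compile_cow_data, compile_herd_data, hc_loglik)
from .records import ObservationSet, ReproductionParams
from .siler import HazardModifiers, SilerParams

__all__ = [
    "Transform", "LOG", "LOGIT", "IDENTITY",
    "param_transform", "param_init",
    "ModelStage", "StageResult", "sequential_fit", "standard_stages",
    "effect_years", "complete_calf_years",
]

# Default priors are normal on the transformed scale and weakly
# informative: sd 2 on log scales (a rate parameter ranges over ~4 orders
# of magnitude around 1), sd 2.5 on logit/identity scales.  A much wider
# sd would concentrate the implied natural-scale prior of any partially
# identified positive parameter at 0 (the 1/x Jacobian dominates along a
# flat likelihood ridge), degrading parameter recovery.
LOG_PRIOR = (0.0, 2.0)
WIDE_PRIOR = (0.0, 2.5)


@dataclass(frozen=True)
class Transform:
    name: str
    forward: Callable[[float], float]   # natural -> sampled
    inverse: Callable[[float], float]   # sampled -> natural


LOG = Transform("log", np.log, np.exp)
LOGIT = Transform("logit",
                  lambda x: np.log(x / (1.0 - x)),
                  lambda z: 1.0 / (1.0 + np.exp(-z)))
IDENTITY = Transform("identity", lambda x: x, lambda z: z)

# name -> (transform, natural-scale init, default prior on the transformed
# scale); per-year parameters are matched by prefix (beta_y_<year>
# identity, f_<year> logit).
_PARAM_TABLE: dict[str, tuple[Transform, float, tuple[float, float]]] = {
    "a1": (LOG, 1.0, LOG_PRIOR),
    "b1": (LOG, 2.0, LOG_PRIOR),
    "a2": (LOG, 0.1, LOG_PRIOR),
    "a3": (LOG, 0.01, LOG_PRIOR),
    "b3": (LOG, 0.3, LOG_PRIOR),
    "beta_s": (IDENTITY, 0.0, WIDE_PRIOR),
    "beta_l": (IDENTITY, 0.0, WIDE_PRIOR),
    "f": (LOGIT, 0.6, WIDE_PRIOR),
    "p": (LOGIT, 0.85, WIDE_PRIOR),
    "q": (LOGIT, 0.05, WIDE_PRIOR),
    "gamma_d": (LOG, 5.0, LOG_PRIOR),
}
_YEARLY = re.compile(r"^(beta_y|f)_(\d{4})$")


def _lookup(name: str) -> tuple[Transform, float, tuple[float, float]]:
    if name in _PARAM_TABLE:
        return _PARAM_TABLE[name]
    m = _YEARLY.match(name)
    if m:
        return (_PARAM_TABLE["f"] if m.group(1) == "f"
                else (IDENTITY, 0.0, WIDE_PRIOR))
    raise KeyError(f"unknown parameter {name!r}")


def param_transform(name: str) -> Transform:
    return _lookup(name)[0]


def param_init(name: str) -> float:
    return _lookup(name)[1]


def default_prior(name: str) -> tuple[float, float]:
    return _lookup(name)[2]


@dataclass
class ModelStage:
    """One fit: a label, the sampled parameter names, and a factory that
    binds the stage's dataset into a log-likelihood over a parameter dict.

    ``fresh`` names parameters this stage estimates from the weak default
    prior even if an earlier stage sampled them.  The hazard curve is
    chained across stages, but each observation model reports its own
    vital rates (fecundity is estimated independently by the herd-count
    and calf-detection models, as the two are reported side by side)."""

    label: str
    params: list[str]
    make_loglik: Callable[[], Callable[[dict], float]]
    fresh: frozenset[str] = frozenset()


@dataclass
class StageResult:
    label: str
    names: list[str]
    chains: PosteriorChains                      # transformed scale
    priors_used: dict[str, tuple[float, float]]  # transformed scale

    def samples(self, name: str) -> np.ndarray:
        """Pooled posterior draws on the natural scale."""
        z = self.chains.pooled(name)
        return np.asarray(param_transform(name).inverse(z))

    def to_frame(self) -> pd.DataFrame:
        """Pooled natural-scale draws, one column per parameter."""
        return pd.DataFrame({n: self.samples(n) for n in self.names})

    @property
    def rhat(self) -> dict[str, float]:
        return self.chains.rhat


def _make_theta(names: Sequence[str], transforms: Sequence[Transform],
                z: np.ndarray) -> dict[str, float]:
    return {n: float(tr.inverse(zi)) for n, tr, zi in zip(names, transforms, z)}


def sequential_fit(
    stages: Sequence[ModelStage],
    seed: int = 0,
    *,
    n_chains: int = 6,
    n_steps: int = 10_000,
    n_burn: Optional[int] = None,
    priors: Optional[dict[str, tuple[float, float]]] = None,
    min_carry_sd: float = 1e-3,
) -> dict[str, StageResult]:
    """Run the stages in order, carrying posteriors forward as priors.

    Each parameter's prior is normal on its transformed scale: the weakly
    informative default if never estimated, otherwise the moment-matched
    normal from the most recent stage that sampled it.  Returns one
    ``StageResult`` per stage label.
    """
    priors = dict(priors or {})
    results: dict[str, StageResult] = {}
    ss = np.random.SeedSequence(seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(stages))]

    for stage, st_seed in zip(stages, stage_seeds):
        names = list(stage.params)
        transforms = [param_transform(n) for n in names]
        used = {n: (default_prior(n) if n in stage.fresh
                    else priors.get(n, default_prior(n))) for n in names}
        mu = np.array([used[n][0] for n in names])
        sd = np.array([used[n][1] for n in names])
        loglik = stage.make_loglik()

        def logpost(z, _mu=mu, _sd=sd, _names=names, _tr=transforms, _ll=loglik):
            lp = -0.5 * float(np.sum(((z - _mu) / _sd) ** 2))
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                theta = _make_theta(_names, _tr, z)
                ll = _ll(theta)
            return lp + ll if np.isfinite(ll) else -np.inf

        init = np.array([tr.forward(param_init(n)) for n, tr in zip(names, transforms)])
        # start carried parameters from their prior means
        for j, n in enumerate(names):
            if n in priors and n not in stage.fresh:
                init[j] = priors[n][0]
        init_scales = np.minimum(sd / 5.0, 0.25)
        chains = metropolis_sample(
            logpost, init, n_chains=n_chains, n_steps=n_steps, seed=st_seed,
            n_burn=n_burn, names=names, init_scales=init_scales)
        res = StageResult(stage.label, names, chains, used)
        results[stage.label] = res
        for n in names:
            z = chains.pooled(n)
            priors[n] = (float(z.mean()), max(float(z.std()), min_carry_sd))
    return results


# ---------------------------------------------------------------------------
# the standard stage battery

def effect_years(data: ObservationSet) -> list[int]:
    """Calendar years eligible for year effects: interior study years
    (incomplete first and last years are excluded)."""
    ys = data.years
    return ys[1:-1] if len(ys) > 2 else ys


def complete_calf_years(data: ObservationSet) -> list[int]:
    """Calf-years with herd counts or detections on both sides of 1 April
    (a proxy for complete within-year coverage); falls back to all."""
    def spans(cy: int) -> bool:
        t = [h.time_since_pulse for h in data.herd_counts if h.calf_year == cy]
        t += [(o.date - _dt.date(cy, 10, 1)).days / 365.25
              for c in data.calf_obs if c.calf_year == cy for o in c.observations]
        return bool(t) and min(t) < 0.5 < max(t)
    cys = data.calf_years
    out = [cy for cy in cys if spans(cy)]
    return out or cys


def _siler_from(theta: Mapping[str, float]) -> SilerParams:
    # stages without immature exposure (adult-only data) omit a1/b1
    return SilerParams(theta.get("a1", 0.0), theta.get("b1", 1.0),
                       theta["a2"], theta["a3"], theta["b3"])


def _mods_from(theta: Mapping[str, float], year_list: Sequence[int]) -> HazardModifiers:
    beta_y: dict[int, float] = {}
    if year_list:
        vals = [theta[f"beta_y_{y}"] for y in year_list[:-1]]
        beta_y = dict(zip(year_list[:-1], vals))
        beta_y[year_list[-1]] = -float(np.sum(vals))  # sum-to-zero constraint
    return HazardModifiers(
        beta_s=theta.get("beta_s", 0.0),
        beta_l=theta.get("beta_l", 0.0),
        beta_y=beta_y,
        gamma_d=theta.get("gamma_d", 0.0),
    )


def standard_stages(
    data: ObservationSet,
    include: Sequence[str] = ("CC", "CC.S", "CC.L", "CC.Y",
                              "HC", "HC.Y", "CD", "CD.Y"),
) -> list[ModelStage]:
    """Build the standard stage sequence for an observation set.

    Stages whose dataset is absent are dropped with the rest of the
    sequence intact (e.g. no calf observations disables CD and CD.Y).
    """
    # Adult-only collared-cow data carry no immature-age exposure, so the
    # CC stages estimate the adult-relevant parameters; the immature
    # component (a1, b1) is estimated where calf data enter (HC, CD).
    adult = ["a2", "a3", "b3"]
    siler = ["a1", "b1", "a2", "a3", "b3"]
    ey = effect_years(data)
    ccy = complete_calf_years(data)
    ccd = compile_cow_data(data.cows) if data.cows else None
    hcd = compile_herd_data(data.herd_counts) if data.herd_counts else None
    cdd = compile_calf_data(data.calf_obs) if data.calf_obs else None

    def cc(theta, mod_years=()):
        return cc_loglik(ccd, _siler_from(theta), _mods_from(theta, mod_years))

    def hc(theta, f_years=None, mod_years=()):
        f = ({cy: theta[f"f_{cy}"] for cy in f_years} if f_years else theta["f"])
        repro = ReproductionParams(f=f)
        return hc_loglik(hcd, repro, _siler_from(theta),
                         _mods_from(theta, mod_years))

    def cd(theta, f_years=None):
        f = ({cy: theta[f"f_{cy}"] for cy in f_years} if f_years else theta["f"])
        repro = ReproductionParams(f=f, p=theta["p"], q=theta["q"])
        return cd_loglik(cdd, repro, _siler_from(theta), _mods_from(theta, ()))

    defs: dict[str, Optional[ModelStage]] = {
        "CC": ModelStage("CC", list(adult), lambda: cc) if ccd else None,
        "CC.S": ModelStage("CC.S", adult + ["beta_s"], lambda: cc) if ccd else None,
        "CC.L": ModelStage("CC.L", adult + ["beta_l"], lambda: cc) if ccd else None,
        "CC.Y": (ModelStage("CC.Y", adult + [f"beta_y_{y}" for y in ey[:-1]],
                            lambda: lambda th: cc(th, ey))
                 if ccd and len(ey) >= 2 else None),
        "HC": (ModelStage("HC", ["f"] + siler + ["beta_s"], lambda: hc)
               if hcd else None),
        "HC.Y": (ModelStage(
            "HC.Y",
            [f"f_{cy}" for cy in ccy] + siler + ["beta_s"]
            + [f"beta_y_{y}" for y in ey[:-1]],
            lambda: lambda th: hc(th, f_years=ccy, mod_years=ey))
            if hcd and len(ccy) >= 2 and len(ey) >= 2 else None),
        "CD": (ModelStage("CD", ["f", "p", "q", "gamma_d"] + siler + ["beta_s"],
                          lambda: cd, fresh=frozenset({"f"}))
               if cdd and cdd.n_records else None),
        "CD.Y": (ModelStage(
            "CD.Y",
            [f"f_{cy}" for cy in sorted(set(ccy)
                                        & {int(y) for y in (cdd.calf_year_levels
                                                            if cdd else [])})]
            + ["p", "q", "gamma_d"] + siler + ["beta_s"],
            lambda: lambda th: cd(th, f_years=sorted(
                set(ccy) & {int(y) for y in cdd.calf_year_levels})),
            fresh=frozenset({f"f_{cy}" for cy in ccy}))
            if cdd and cdd.n_records and len(ccy) >= 2 else None),
    }
    out = []
    for label in include:
        if label not in defs:
            raise KeyError(f"unknown stage {label!r}")
        st = defs[label]
        if st is not None:
            out.append(st)
    return out
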