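"""Derived vital-rate quantities computed draw-by-draw from posteriors.

Following the chain-functional convention, every derived quantity
(first-year survivorship, recruitment, longevity, life expectancy, annual
survival at an age) is computed by applying its definition to each
posterior draw, so that credible intervals of derived rates come directly
from the propagated parameter uncertainty.
"""

from __future__ import annotations

import datetime as _dt
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import seasons
from .likelihoods import _calf_segments
from .siler import SilerParams, life_expectancy, longevity

__all__ = [
    "path_survivorship_samples",
    "s1_samples",
    "recruitment_samples",
    "hazard_samples",
    "annual_survival_samples",
    "longevity_samples",
    "life_expectancy_samples",
]


def _col(frame: pd.DataFrame, name: str, default: float = 0.0) -> np.ndarray:
    if name in frame.columns:
        return frame[name].to_numpy(dtype=float)
    return np.full(len(frame), default)


def path_survivorship_samples(
    frame: pd.DataFrame,
    t: float,
    calf_year: int = 2015,
    location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
) -> np.ndarray:
    """Per-draw survivorship from the birth pulse to age ``t`` along the
    canonical migratory path, vectorized over the posterior draws in
    ``frame`` (columns a1, b1, a2, a3, b3 and optionally beta_s, beta_l,
    beta_y_<year>)."""
    a1 = _col(frame, "a1")
    b1 = _col(frame, "b1", 1.0)
    a2 = _col(frame, "a2")
    a3 = _col(frame, "a3")
    b3 = _col(frame, "b3", 1.0)
    bs = _col(frame, "beta_s")
    bl = _col(frame, "beta_l")
    H = np.zeros(len(frame))
    for (lo, hi, wet, loc, year) in _calf_segments(calf_year, t, location_fn):
        dH = (a1 / b1 * (np.exp(-b1 * lo) - np.exp(-b1 * hi))
              + a2 * (hi - lo)
              + a3 / b3 * (np.exp(b3 * hi) - np.exp(b3 * lo)))
        by = _col(frame, f"beta_y_{year}")
        H += np.exp(bs * wet + bl * loc + by) * dH
    return np.exp(-H)


def s1_samples(frame: pd.DataFrame, calf_year: int = 2015,
               location_fn: Callable[[_dt.date], float] = seasons.migratory_location,
               ) -> np.ndarray:
    """Per-draw first-year survivorship S1 (birth pulse to age 1.0)."""
    return path_survivorship_samples(frame, 1.0, calf_year, location_fn)


def recruitment_samples(frame: pd.DataFrame, to_age: float = 1.0,
                        calf_year: int = 2015,
                        f_column: str = "f") -> np.ndarray:
    """Per-draw recruitment to ``to_age``: fecundity times survivorship to
    that age (expected surviving offspring per cow)."""
    f = frame[f_column].to_numpy(dtype=float)
    return f * path_survivorship_samples(frame, to_age, calf_year)


def hazard_samples(frame: pd.DataFrame, age: float) -> np.ndarray:
    """Per-draw baseline Siler hazard at an age."""
    a1, b1 = _col(frame, "a1"), _col(frame, "b1", 1.0)
    a2 = _col(frame, "a2")
    a3, b3 = _col(frame, "a3"), _col(frame, "b3", 1.0)
    return a1 * np.exp(-b1 * age) + a2 + a3 * np.exp(b3 * age)


def annual_survival_samples(frame: pd.DataFrame, age: float) -> np.ndarray:
    """Per-draw instantaneous annualized survival exp(-h(age))."""
    return np.exp(-hazard_samples(frame, age))


def _thinned(frame: pd.DataFrame, max_draws: Optional[int], seed: int) -> pd.DataFrame:
    if max_draws is None or len(frame) <= max_draws:
        return frame
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frame), size=max_draws, replace=False)
    return frame.iloc[np.sort(idx)]

def _params_iter(frame: pd.DataFrame):
    for row in frame.itertuples(index=False):
        yield SilerParams(getattr(row, "a1", 0.0), getattr(row, "b1", 1.0),
                          row.a2, row.a3, row.b3)


def longevity_samples(frame: pd.DataFrame, quantile: float = 0.001,
                      max_draws: Optional[int] = 2000, seed: int = 0) -> np.ndarray:
    """Per-draw longevity (age reached by the stated fraction, default 0.1%).

    Root-finding per draw; ``max_draws`` thins very long chains."""
    sub = _thinned(frame, max_draws, seed)
    return np.array([longevity(p, quantile) for p in _params_iter(sub)])


def life_expectancy_samples(frame: pd.DataFrame,
                            max_draws: Optional[int] = 2000,
                            seed: int = 0) -> np.ndarray:
    """Per-draw life expectancy at birth (numerical survivorship integral)."""
    sub = _thinned(frame, max_draws, seed)
    return np.array([life_expectancy(p) for p in _params_iter(sub)])
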