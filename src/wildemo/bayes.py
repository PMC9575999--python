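"""Random-walk Metropolis sampling and posterior inference metrics.

Sampling happens on transformed scales (log for positive parameters, logit
for probabilities, identity for signed effects) so that weak normal priors
are proper and scale-free and proposals are unconstrained.  The proposal
covariance is adapted during burn-in only and frozen afterward, which
preserves detailed balance for the retained draws.

Inference metrics follow the evidence-ratio framework: expected values
(EV), shortest highest-posterior-density credible intervals (HPD, default
mass 90.9% = 10/11 so that the interval itself corresponds to an evidence
ratio of 10, i.e. "strong"), one-sided lower credible limits (LCL0),
probabilities of exceeding zero (Pr>0), and log10 evidence ratios
LER = log10(Pr / (1-Pr)) with 0.5 / 1.0 / 1.5 / 2.0 read as substantial /
strong / very strong / decisive.

Interannual variation among a vector of hazards h is summarized by
maxR = exp(range(ln h)) and meanR = exp(mean |ln h_i - ln h_j|) over all
unordered year pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "DEFAULT_CREDIBLE_LEVEL",
    "PosteriorChains",
    "metropolis_sample",
    "split_rhat",
    "ev",
    "hpd_interval",
    "lcl0",
    "pr_gt0",
    "evidence_ratio",
    "log_evidence_ratio",
    "interpret_ler",
    "interannual_ratios",
    "annual_hazard_from_s1",
]

#: Credible level for which the interval itself is "strong" evidence:
#: ER = level / (1 - level) = 10, hence level = 10/11 = 90.9%.
DEFAULT_CREDIBLE_LEVEL = 10.0 / 11.0


@dataclass
class PosteriorChains:
    """Post-burn-in Metropolis samples on the sampled (transformed) scale.

    samples : array (n_chains, n_steps_kept, n_params)
    """

    names: list[str]
    samples: np.ndarray
    n_burn: int
    acceptance: np.ndarray          # per chain, post-burn-in
    proposal_scales: np.ndarray     # per chain, frozen scales
    seed: Optional[int] = None
    rhat: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples.ndim != 3:
            raise ValueError("samples must be (chains, steps, params)")
        if self.samples.shape[2] != len(self.names):
            raise ValueError("names/samples mismatch")

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_steps(self) -> int:
        return self.samples.shape[1]

    def pooled(self, name: Optional[str] = None) -> np.ndarray:
        """Pool all chains; 1-D for a named parameter, else (n, d)."""
        flat = self.samples.reshape(-1, self.samples.shape[2])
        if name is None:
            return flat
        return flat[:, self.names.index(name)]


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential-scale-reduction diagnostic for one parameter.

    ``x`` has shape (n_chains, n_steps); each chain is split in half, giving
    2*n_chains sequences.
    """
    n_chains, n = x.shape
    half = n // 2
    seqs = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return np.inf if B > 0 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def metropolis_sample(
    logpost: Callable[[np.ndarray], float],
    init: Sequence[float],
    n_chains: int = 6,
    n_steps: int = 10_000,
    seed: int = 0,
    *,
    n_burn: Optional[int] = None,
    names: Optional[Sequence[str]] = None,
    init_scales: Optional[Sequence[float]] = None,
    target_acceptance: float = 0.28,
    adapt_window: int = 100,
    jitter: float = 0.1,
) -> PosteriorChains:
    """Adaptive random-walk Metropolis.

    Runs ``n_chains`` chains for ``n_burn + n_steps`` iterations each
    (``n_burn`` defaults to ``n_steps``, i.e. the first half of the run is
    discarded) and keeps the final ``n_steps`` states.  During burn-in the
    proposal covariance is re-estimated from the chain's own history
    (scaled by 2.38/sqrt(d), so the walk aligns with posterior
    correlations) and a global factor is tuned toward the target
    acceptance rate (20-40% band); both are frozen at the end of burn-in
    so the retained draws target the exact posterior.  Chains start from
    ``init`` with small jittered offsets.  Fully reproducible under a
    fixed seed.
    """
    init = np.asarray(init, dtype=float)
    d = init.size
    if n_burn is None:
        n_burn = n_steps
    lp0 = float(logpost(init))
    if not np.isfinite(lp0):
        raise ValueError("logpost is not finite at init")
    if names is None:
        names = [f"p{i}" for i in range(d)]
    scales0 = (np.full(d, 0.1) if init_scales is None
               else np.asarray(init_scales, dtype=float))
    opt = 2.38 / np.sqrt(d)  # optimal random-walk scaling for Gaussian targets

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chains)
    kept = np.empty((n_chains, n_steps, d))
    acc_rates = np.empty(n_chains)
    final_scales = np.empty((n_chains, d))

    for c in range(n_chains):
        rng = np.random.default_rng(child_seeds[c])
        z = init + jitter * scales0 * rng.standard_normal(d)
        lp = float(logpost(z))
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            z = init + jitter * scales0 * rng.standard_normal(d)
            lp = float(logpost(z))
            tries += 1
        if not np.isfinite(lp):
            z, lp = init.copy(), lp0
        # proposal: z' = z + gfac * L @ N(0, I); L starts diagonal and is
        # re-estimated from the burn-in history (full covariance), so the
        # walk aligns with posterior correlations; frozen after burn-in
        L = np.diag(scales0)
        gfac = 1.0
        burn_acc = 0
        win_acc = 0
        history = np.empty((n_burn, d))
        for t in range(n_burn + n_steps):
            prop = z + gfac * (L @ rng.standard_normal(d))
            lp_prop = float(logpost(prop))
            if np.log(rng.uniform()) < lp_prop - lp:
                z, lp = prop, lp_prop
                if t < n_burn:
                    burn_acc += 1
                win_acc += 1
            if t < n_burn:
                history[t] = z
                if (t + 1) % adapt_window == 0:
                    rate = win_acc / adapt_window
                    gfac *= float(np.exp(1.2 * (rate - target_acceptance)))
                    gfac = float(np.clip(gfac, 1e-4, 1e4))
                    win_acc = 0
                    if t + 1 >= max(200, n_burn // 4):
                        sub = history[(t + 1) // 2: t + 1]
                        cov = np.cov(sub.T) if d > 1 else np.array(
                            [[sub.var()]])
                        cov = np.atleast_2d(cov)
                        cov[np.diag_indices(d)] += (1e-4 * scales0) ** 2
                        try:
                            L = opt * np.linalg.cholesky(cov)
                            gfac = 1.0
                        except np.linalg.LinAlgError:
                            pass
                if t == n_burn - 1:
                    if burn_acc == 0:
                        raise RuntimeError(
                            f"chain {c}: no proposal accepted during burn-in; "
                            "check the posterior or initial values")
                    win_acc = 0
            else:
                kept[c, t - n_burn] = z
        acc_rates[c] = win_acc / n_steps
        final_scales[c] = gfac * np.sqrt(np.diag(L @ L.T))

    chains = PosteriorChains(
        names=list(names), samples=kept, n_burn=n_burn,
        acceptance=acc_rates, proposal_scales=final_scales, seed=seed)
    for j, nm in enumerate(names):
        chains.rhat[nm] = split_rhat(kept[:, :, j]) if n_chains * n_steps >= 4 else np.nan
    return chains


# ---------------------------------------------------------------------------
# posterior summaries

def _pooled(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no samples")
    return x


def ev(samples) -> float:
    """Expected value (pooled posterior mean)."""
    return float(np.mean(_pooled(samples)))


def hpd_interval(samples, level: float = DEFAULT_CREDIBLE_LEVEL) -> tuple[float, float]:
    """Shortest interval containing the stated posterior mass.

    If the posterior is multimodal the shortest single interval is returned
    (the standard resolution of HPD ambiguity for interval reporting).
    """
    x = np.sort(_pooled(samples))
    n = x.size
    k = max(1, int(np.ceil(level * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def lcl0(samples, level: float = DEFAULT_CREDIBLE_LEVEL) -> float:
    """One-sided lower credible limit: P(theta > LCL0) = level."""
    return float(np.quantile(_pooled(samples), 1.0 - level))


def pr_gt0(samples) -> float:
    """Posterior probability of being greater than zero."""
    x = _pooled(samples)
    return float(np.mean(x > 0))


def evidence_ratio(pr: float) -> float:
    """ER = Pr / (1 - Pr).  At Pr in {0, 1} the ratio exceeds the Monte
    Carlo resolution and is reported as the corresponding bound (0 or inf)."""
    if not 0.0 <= pr <= 1.0:
        raise ValueError("pr must be in [0, 1]")
    if pr in (0.0, 1.0):
        warnings.warn("Pr at the Monte Carlo resolution limit; "
                      "evidence ratio reported as a bound")
        return np.inf if pr == 1.0 else 0.0
    return pr / (1.0 - pr)


def log_evidence_ratio(pr: float) -> float:
    """LER = log10(ER)."""
    return float(np.log10(evidence_ratio(pr)))


def interpret_ler(ler: float) -> str:
    """Verbal evidence category for a log10 evidence ratio."""
    a = abs(ler)
    if a >= 2.0:
        return "decisive"
    if a >= 1.5:
        return "very strong"
    if a >= 1.0:
        return "strong"
    if a >= 0.5:
        return "substantial"
    return "weak"


def interannual_ratios(hazards) -> tuple:
    """(maxR, meanR) among a vector of positive annual hazard levels.

    maxR = exp(max ln h - min ln h); meanR = exp(mean |ln h_i - ln h_j|)
    over all unordered year pairs.  A 2-D input (draws, years) is reduced
    per draw, returning two arrays.  Both ratios are >= 1 and invariant to
    scaling all hazards by a common factor (year-effect identifiability).
    """
    h = np.asarray(hazards, dtype=float)
    if np.any(h <= 0):
        raise ValueError("hazards must be > 0")
    one_d = h.ndim == 1
    h = np.atleast_2d(h)
    k = h.shape[1]
    if k < 2:
        raise ValueError("need >= 2 years")
    lnh = np.log(h)
    maxR = np.exp(lnh.max(axis=1) - lnh.min(axis=1))
    diffs = np.abs(lnh[:, :, None] - lnh[:, None, :])
    meanR = np.exp(diffs.sum(axis=(1, 2)) / (k * (k - 1)))
    if one_d:
        return float(maxR[0]), float(meanR[0])
    return maxR, meanR


def annual_hazard_from_s1(s1) -> Union[float, np.ndarray]:
    """Mean first-year hazard from first-year survivorship: h1 = -ln(S1)."""
    s1 = np.asarray(s1, dtype=float)
    out = -np.log(s1)
    return out if out.ndim else float(out)
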