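"""Adaptive random-walk Metropolis sampling, convergence diagnostics and DIC.

The sampler is a Gaussian random-walk Metropolis–Hastings with per-parameter
proposal scales.  Scales adapt multiplicatively toward a target acceptance
band during burn-in only and are frozen afterwards, so the retained draws
come from a proper (non-adaptive) Markov chain.  Multiple chains started
from dispersed initial values feed the classic Gelman–Rubin potential scale
reduction factor, and model comparison uses the Spiegelhalter DIC
(mean deviance plus pD = mean deviance minus deviance at the posterior
mean).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration.

    Defaults follow the full-scale protocol (5 chains of 150 000 steps, the
    first half discarded as burn-in, thinning every 10 steps); shorter runs
    are configured explicitly where used.
    """

    n_chains: int = 5
    n_steps: int = 150_000
    burn_in_fraction: float = 0.5
    thin: int = 10
    seed: int = 0
    init_proposal_scale: float = 0.1
    adapt_window: int = 100
    target_accept: tuple[float, float] = (0.15, 0.45)

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_steps < 1 or self.thin < 1:
            raise ValueError("chain counts, steps and thinning must be positive")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in (0, 1)")
        lo, hi = self.target_accept
        if not 0 < lo < hi < 1:
            raise ValueError("invalid target acceptance band")
        if self.n_retained < 10:
            raise ValueError("settings retain fewer than 10 draws per chain")

    @property
    def n_burn(self) -> int:
        return int(self.n_steps * self.burn_in_fraction)

    @property
    def n_retained(self) -> int:
        """Retained draws per chain after burn-in and thinning."""
        return (self.n_steps - int(self.n_steps * self.burn_in_fraction)) // self.thin


@dataclass
class PosteriorSample:
    """Stacked multi-chain draws with per-draw log-posterior and deviance.

    ``draws`` has shape (n_chains, n_retained, n_params).
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    log_posterior: np.ndarray
    deviance: np.ndarray | None = None
    deviance_at_mean: float | None = None
    accept_rate: np.ndarray | None = None
    proposal_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if not np.isfinite(self.draws).all():
            raise ValueError("non-finite posterior draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: (n_chains * n_retained, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        c, n, p = self.draws.shape
        frame = pd.DataFrame(self.stacked(), columns=list(self.param_names))
        frame.insert(0, "iteration", np.tile(np.arange(n), c))
        frame.insert(0, "chain", np.repeat(np.arange(c), n))
        frame["log_posterior"] = self.log_posterior.reshape(-1)
        if self.deviance is not None:
            frame["deviance"] = self.deviance.reshape(-1)
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            frame.to_csv(fh, index=False)


def rw_metropolis_chain(logpost, init, settings: McmcSettings,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One adaptive random-walk Metropolis chain.

    Proposals are ``theta + scales * N(0, I)`` with per-parameter scales.
    During burn-in the scales adapt every ``adapt_window`` steps in the
    Haario spirit: each parameter's scale tracks the spread of its recent
    draws (so anisotropic posteriors get anisotropic steps), and a common
    multiplier is nudged until the window acceptance rate sits in the
    target band.  Adaptation stops at the end of burn-in, so the retained
    draws come from a fixed-kernel Markov chain.  Returns the full
    step-by-step chain, its log-posterior trace, the post-burn-in
    acceptance rate and the frozen proposal scales.
    """
    rng = np.random.default_rng(settings.seed) if rng is None else rng
    theta = np.asarray(init, dtype=float).copy()
    lp = logpost(theta)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial value")
    p = theta.size
    base = np.full(p, settings.init_proposal_scale, dtype=float)
    if (base <= 0).any():
        raise ValueError("zero proposal scale")
    factor = 1.0
    scales = factor * base
    chain = np.empty((settings.n_steps, p))
    lps = np.empty(settings.n_steps)
    window_accepts = 0
    post_accepts = 0
    lo, hi = settings.target_accept
    mid = 0.5 * (lo + hi)
    spread_target = 2.4 / np.sqrt(p)  # Haario et al. scaling for RW proposals
    for step in range(settings.n_steps):
        proposal = theta + scales * rng.standard_normal(p)
        lp_prop = logpost(proposal)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = proposal, lp_prop
            window_accepts += 1
            if step >= settings.n_burn:
                post_accepts += 1
        chain[step] = theta
        lps[step] = lp
        if step < settings.n_burn and (step + 1) % settings.adapt_window == 0:
            rate = window_accepts / settings.adapt_window
            factor *= float(np.exp(rate - mid))
            recent = chain[max(0, step + 1 - 5 * settings.adapt_window): step + 1]
            spread = recent.std(axis=0)
            moved = spread > 0
            base[moved] = spread_target * spread[moved]
            scales = factor * base
            window_accepts = 0
        elif step == settings.n_burn - 1:
            window_accepts = 0
    n_post = settings.n_steps - settings.n_burn
    return chain, lps, post_accepts / max(n_post, 1), scales


def run_multichain(logpost, inits, settings: McmcSettings,
                   loglik=None, param_names: tuple[str, ...] | None = None,
                   ) -> PosteriorSample:
    """Run ``n_chains`` chains from distinct starting points and stack them.

    Burn-in is dropped and the remainder thinned per ``settings``.  Child
    seeds for the chains are spawned deterministically from ``settings.seed``.
    When ``loglik`` is supplied, per-draw deviance D = -2 LL and the deviance
    at the posterior-mean coefficients are recorded for DIC.
    """
    inits = [np.asarray(v, dtype=float) for v in inits]
    if len(inits) < settings.n_chains:
        raise ValueError(f"{settings.n_chains} chains need as many initial values")
    p = inits[0].size
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    draws = np.empty((settings.n_chains, settings.n_retained, p))
    lps = np.empty((settings.n_chains, settings.n_retained))
    rates = np.empty(settings.n_chains)
    scales = np.empty((settings.n_chains, p))
    keep = slice(settings.n_burn + settings.thin - 1, settings.n_steps, settings.thin)
    for c in range(settings.n_chains):
        rng = np.random.default_rng(seeds[c])
        chain, lp_trace, rates[c], scales[c] = rw_metropolis_chain(
            logpost, inits[c], settings, rng=rng)
        draws[c] = chain[keep][: settings.n_retained]
        lps[c] = lp_trace[keep][: settings.n_retained]
    names = param_names or tuple(f"beta_{k}" for k in range(p))
    sample = PosteriorSample(draws, tuple(names), lps,
                             accept_rate=rates, proposal_scales=scales)
    if loglik is not None:
        flat = sample.stacked()
        dev = -2.0 * np.array([loglik(b) for b in flat])
        sample.deviance = dev.reshape(settings.n_chains, settings.n_retained)
        sample.deviance_at_mean = float(-2.0 * loglik(flat.mean(axis=0)))
    return sample


def gelman_rubin(sample: PosteriorSample) -> np.ndarray:
    """Classic potential scale reduction factor per parameter.

    PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the between-chain variance of the chain means.
    Requires at least two chains; NaN is returned instead for one chain.
    """
    c, n, p = sample.draws.shape
    if c < 2 or n < 2:
        return np.full(p, np.nan)
    means = sample.draws.mean(axis=1)                     # (c, p)
    W = sample.draws.var(axis=1, ddof=1).mean(axis=0)     # (p,)
    if (W == 0).any():
        raise ValueError("degenerate chains: zero within-chain variance")
    B_over_n = means.var(axis=0, ddof=1)                  # = B / n
    var_hat = (n - 1) / n * W + B_over_n
    return np.sqrt(var_hat / W)


def dic(sample: PosteriorSample) -> tuple[float, float]:
    """Deviance Information Criterion and effective parameter count.

    DIC = Dbar + pD with pD = Dbar - D(posterior mean).  Returns
    (DIC, pD); the sample must carry deviances (fit with a likelihood).
    """
    if sample.deviance is None or sample.deviance_at_mean is None:
        raise ValueError("sample has no stored deviance; refit with loglik")
    if not np.isfinite(sample.deviance_at_mean):
        raise ValueError("deviance at the posterior mean is not finite")
    dbar = float(sample.deviance.mean())
    pd_eff = dbar - sample.deviance_at_mean
    return dbar + pd_eff, pd_eff


def posterior_summary(sample: PosteriorSample) -> pd.DataFrame:
    """Per-parameter median, central 95% credible interval and R-hat."""
    flat = sample.stacked()
    if flat.size == 0:
        raise ValueError("empty posterior sample")
    med = np.median(flat, axis=0)
    q_lo, q_hi = np.quantile(flat, [0.025, 0.975], axis=0)
    try:
        rhat = gelman_rubin(sample)
    except ValueError:
        rhat = np.full(flat.shape[1], np.nan)
    return pd.DataFrame({
        "parameter": list(sample.param_names),
        "median": med,
        "ci_2.5": q_lo,
        "ci_97.5": q_hi,
        "rhat": rhat,
    })


def dispersed_inits(n_chains: int, n_params: int, priors, seed: int,
                    bound: float = 5.0, logpost=None, center=None,
                    dispersion: float = 1.0,
                    max_tries: int = 1000) -> list[np.ndarray]:
    """Chain starting points: prior draws truncated to |offset| <= bound,
    scaled by ``dispersion`` and dispersed around ``center`` (default 0).

    When ``logpost`` is given, draws with a non-finite log-posterior (e.g.
    aggregated proportions pushed past 1) are rejected and redrawn, the
    offsets shrinking toward the center if rejection persists.
    """
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    scales = priors.scales(n_params)
    center = np.zeros(n_params) if center is None else np.asarray(center, dtype=float)
    inits = []
    for s in seqs:
        rng = np.random.default_rng(s)
        for attempt in range(max_tries):
            offset = scales * rng.standard_cauchy(n_params)
            while (np.abs(offset) > bound).any():
                bad = np.abs(offset) > bound
                offset[bad] = scales[bad] * rng.standard_cauchy(bad.sum())
            draw = center + dispersion * offset * 0.5 ** (attempt // 5)
            if logpost is None or np.isfinite(logpost(draw)):
                break
        else:
            raise ValueError("could not find a finite starting point")
        inits.append(draw)
    return inits


def with_seed(settings: McmcSettings, seed: int) -> McmcSettings:
    return replace(settings, seed=seed)
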