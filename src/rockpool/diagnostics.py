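"""Convergence and goodness-of-fit diagnostics for the MCMC output.

Split-chain Gelman-Rubin potential scale reduction (values < 1.1 were the
convergence standard for these models) and posterior predictive checks of
the response mean and variance, summarised as Bayesian p-values (values
near 0.5 indicate the observation model reproduces the statistic well).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PpcResult", "gelman_rubin", "gelman_rubin_all", "ppc_pvalues"]


@dataclass(frozen=True)
class PpcResult:
    """Bayesian p-values for the mean and the variance of the response."""

    p_mean: float
    p_var: float

    def __post_init__(self) -> None:
        for v in (self.p_mean, self.p_var):
            if not 0.0 <= v <= 1.0:
                raise ValueError("Bayesian p-values must lie in [0, 1]")


def gelman_rubin(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``draws`` has shape (chains, iterations). Each chain is split in half,
    so mixing failures within a chain are also detected. Chains with zero
    within-chain variance (constant chains) are degenerate; a warning is
    issued and 1.0 returned if the between-chain variance is also zero.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must have shape (chains, iterations)")
    c, s = draws.shape
    if c < 2:
        raise ValueError(
            "Gelman-Rubin requires >= 2 chains; re-run with n_chains >= 2"
        )
    half = s // 2
    split = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    m, length = split.shape
    chain_means = split.mean(axis=1)
    w = float(split.var(axis=1, ddof=1).mean())
    b = length * float(chain_means.var(ddof=1))
    if w <= 0.0:
        if b <= 0.0:
            warnings.warn(
                "degenerate chains: zero within- and between-chain variance",
                stacklevel=2,
            )
            return 1.0
        return float("inf")
    var_plus = (length - 1) / length * w + b / length
    return float(np.sqrt(var_plus / w))


def gelman_rubin_all(param_draws: dict[str, np.ndarray]) -> dict[str, float]:
    """R-hat for every parameter in a name -> (chains, iterations) mapping."""
    return {name: gelman_rubin(d) for name, d in param_draws.items()}


def ppc_pvalues(results, seed: int, redraw_random_effects: bool = False) -> PpcResult:
    """Posterior predictive checks of the mean and variance.

    For each retained draw, a replicate response vector is simulated from
    the fitted observation model — by default re-drawing only the residual
    error conditional on the sampled random effects; with
    ``redraw_random_effects`` the random-effect levels are re-drawn from
    their population distributions as well. The p-values are the fraction
    of replicates whose statistic is at least the observed statistic.
    """
    return results._ppc(seed=seed, redraw_random_effects=redraw_random_effects)
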