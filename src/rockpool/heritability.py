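"""Broad-sense heritability and temperature contrasts from posterior draws.

In a clonal design, among-clone variance is (total) genetic variance, so
broad-sense heritability is computed draw-wise as

    H2 = sigma_clone^2 / (sigma_clone^2 + sigma_error^2)

i.e. the clone variance over clone-plus-error phenotypic variance. The
assay-batch (trial) variance, when present, is excluded from the
denominator: H2 is the heritability of the assay-adjusted phenotype.
Summaries are posterior medians with central 95% credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeritabilityEstimate", "TemperatureContrast",
           "heritability_from_draws", "contrast_from_draws"]


def _summ(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Posterior V_G, V_E and H2 for one group (a temperature or a pool)."""

    group: str
    v_g: tuple[float, float, float]   # (median, lo95, hi95), response units^2
    v_e: tuple[float, float, float]
    h2: tuple[float, float, float]
    v_g_draws: np.ndarray
    v_e_draws: np.ndarray
    h2_draws: np.ndarray


@dataclass(frozen=True)
class TemperatureContrast:
    """Per-draw 20 degC minus 25 degC differences and percent changes.

    ``*_diff`` are (median, lo95, hi95) of the draw-wise difference
    (value at 20 minus value at 25); ``*_pct_change`` is the change of the
    posterior medians from 20 to 25, as (median25 - median20)/median20 * 100.
    When ``percent_draws`` summaries are present they are the per-draw
    percent-change credible intervals (optional alternative summary).
    """

    v_g_diff: tuple[float, float, float]
    v_e_diff: tuple[float, float, float]
    h2_diff: tuple[float, float, float]
    v_g_pct_change: float
    v_e_pct_change: float
    h2_pct_change: float
    percent_draws: dict[str, tuple[float, float, float]] | None = None


def heritability_from_draws(
    group: str, sigma_clone: np.ndarray, sigma_error: np.ndarray
) -> HeritabilityEstimate:
    """Summarise V_G, V_E, H2 from SD draws for one group."""
    sigma_clone = np.asarray(sigma_clone, dtype=float).ravel()
    sigma_error = np.asarray(sigma_error, dtype=float).ravel()
    if sigma_clone.shape != sigma_error.shape:
        raise ValueError("clone and error draw vectors must align")
    v_g = sigma_clone ** 2
    v_e = sigma_error ** 2
    h2 = v_g / (v_g + v_e)
    return HeritabilityEstimate(
        group=str(group),
        v_g=_summ(v_g), v_e=_summ(v_e), h2=_summ(h2),
        v_g_draws=v_g, v_e_draws=v_e, h2_draws=h2,
    )


def _pct(med20: float, med25: float) -> float:
    return (med25 - med20) / med20 * 100.0


def contrast_from_draws(
    est20: HeritabilityEstimate,
    est25: HeritabilityEstimate,
    per_draw_percent: bool = False,
) -> TemperatureContrast:
    """Temperature contrast (20 vs 25 degC) of V_G, V_E and H2."""
    pct_draws = None
    if per_draw_percent:
        pct_draws = {
            "v_g": _summ((est25.v_g_draws - est20.v_g_draws)
                         / est20.v_g_draws * 100.0),
            "v_e": _summ((est25.v_e_draws - est20.v_e_draws)
                         / est20.v_e_draws * 100.0),
            "h2": _summ((est25.h2_draws - est20.h2_draws)
                        / est20.h2_draws * 100.0),
        }
    return TemperatureContrast(
        v_g_diff=_summ(est20.v_g_draws - est25.v_g_draws),
        v_e_diff=_summ(est20.v_e_draws - est25.v_e_draws),
        h2_diff=_summ(est20.h2_draws - est25.h2_draws),
        v_g_pct_change=_pct(est20.v_g[0], est25.v_g[0]),
        v_e_pct_change=_pct(est20.v_e[0], est25.v_e[0]),
        h2_pct_change=_pct(est20.h2[0], est25.h2[0]),
        percent_draws=pct_draws,
    )
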