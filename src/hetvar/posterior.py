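"""Posterior summaries, derived genetic parameters and the Geweke diagnostic.

Summaries report both the posterior standard deviation and the Monte-Carlo
standard error of the posterior mean; the latter uses a batch-means estimate
of the spectral density at zero, which also drives the Geweke convergence
z-score.  Credible intervals are equal-tailed (2.5/97.5 empirical quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PosteriorSummary", "derived_parameters", "summarize_draws",
    "batch_means_variance", "geweke_z", "ci_overlap", "summary_table",
]


@dataclass
class PosteriorSummary:
    """One row of a posterior summary table."""

    mean: float
    mc_sd: float          # Monte-Carlo standard error of the mean
    posterior_sd: float
    median: float
    ci95: tuple[float, float]
    geweke_z: float
    geweke_p: float


def derived_parameters(draws: pd.DataFrame) -> pd.DataFrame:
    """Per-draw heritabilities (and genetic correlation for bivariate draws).

    Single-trait draw tables (columns ``sigma2_a``, ``sigma2_e``) yield
    ``h2 = sigma2_a / (sigma2_a + sigma2_e)``.  Bivariate tables
    (``sigma2_a_low``, ``sigma2_a_high``, ``sigma_a_lh``, ``sigma2_e_low``,
    ``sigma2_e_high``) yield ``h2_low``, ``h2_high`` and
    ``rg = sigma_a_lh / sqrt(sigma2_a_low * sigma2_a_high)``.
    """
    out = pd.DataFrame(index=draws.index)
    if "sigma2_a" in draws.columns:
        tot = draws["sigma2_a"] + draws["sigma2_e"]
        if (tot <= 0).any():
            raise ValueError("non-positive phenotypic variance draw")
        out["h2"] = draws["sigma2_a"] / tot
        return out
    for cls in ("low", "high"):
        tot = draws[f"sigma2_a_{cls}"] + draws[f"sigma2_e_{cls}"]
        if (tot <= 0).any():
            raise ValueError("non-positive phenotypic variance draw")
        out[f"h2_{cls}"] = draws[f"sigma2_a_{cls}"] / tot
    out["rg"] = draws["sigma_a_lh"] / np.sqrt(
        draws["sigma2_a_low"] * draws["sigma2_a_high"]
    )
    return out


def batch_means_variance(values: np.ndarray) -> float:
    """Estimated variance of the mean of a correlated chain.

    Nonoverlapping batch means with about sqrt(n) batches; the variance of
    the batch means divided by the number of batches estimates
    ``spectral_density_at_zero / n``, i.e. the squared Monte-Carlo standard
    error of the chain mean.  Falls back to the IID formula for chains too
    short to batch.
    """
    x = np.asarray(values, float)
    n = x.size
    m = int(np.sqrt(n))
    if m < 2:
        return float(np.var(x, ddof=1) / n) if n > 1 else np.nan
    b = n // m
    batches = x[: m * b].reshape(m, b).mean(axis=1)
    return float(np.var(batches, ddof=1) / m)


def geweke_z(values, first_frac: float = 0.1, last_frac: float = 0.5):
    """Geweke convergence diagnostic: compare early vs late window means.

    ``z = (mean_first - mean_last) / sqrt(v_first + v_last)`` where each
    ``v`` is the batch-means estimate of the variance of the window mean;
    ``p`` is the two-sided standard-normal tail.  A stationary, converged
    chain gives |z| below 1.96 about 95% of the time.
    """
    x = np.asarray(values, float)
    n = x.size
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    if n1 < 4 or n2 < 4:
        raise ValueError("chain too short for the requested Geweke windows")
    first, last = x[:n1], x[n - n2:]
    v1 = batch_means_variance(first)
    v2 = batch_means_variance(last)
    if v1 + v2 == 0:
        if np.var(first) + np.var(last) == 0:
            raise ValueError("zero variance in a Geweke window")
        # periodic chains can zero the batch means while the window itself
        # varies; fall back to the IID variance of the window mean
        v1 = np.var(first, ddof=1) / n1
        v2 = np.var(last, ddof=1) / n2
    z = (first.mean() - last.mean()) / np.sqrt(v1 + v2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def summarize_draws(values) -> PosteriorSummary:
    """Summary of one scalar chain: mean, MCSE, SD, median, 95% CI, Geweke."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least two draws to summarize")
    lo, hi = np.quantile(x, [0.025, 0.975])
    try:
        gz, gp = geweke_z(x)
    except ValueError:
        gz, gp = np.nan, np.nan
    return PosteriorSummary(
        mean=float(x.mean()),
        mc_sd=float(np.sqrt(batch_means_variance(x))),
        posterior_sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        ci95=(float(lo), float(hi)),
        geweke_z=gz,
        geweke_p=gp,
    )


def ci_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff the two closed intervals intersect (touching counts)."""
    for lo, hi in (a, b):
        if lo > hi:
            raise ValueError(f"interval [{lo}, {hi}] has lower > upper")
    return max(a[0], b[0]) <= min(a[1], b[1])


def summary_table(draws: pd.DataFrame, analysis: str,
                  include_derived: bool = True) -> pd.DataFrame:
    """Summaries of every variance column plus derived h2/rg chains."""
    chains = draws.copy()
    if include_derived:
        chains = pd.concat([chains, derived_parameters(draws)], axis=1)
    rows = []
    for name, col in chains.items():
        s = summarize_draws(col.to_numpy())
        rows.append({
            "parameter": name, "analysis": analysis, "mean": s.mean,
            "mc_sd": s.mc_sd, "posterior_sd": s.posterior_sd,
            "median": s.median, "ci_low": s.ci95[0], "ci_high": s.ci95[1],
            "geweke_z": s.geweke_z, "geweke_p": s.geweke_p,
        })
    return pd.DataFrame(rows)
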