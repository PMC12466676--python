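"""Cross-analysis statistics: heritability Z-test, sire EBV rank
correlations, and EBV regressions between the general and class-specific
evaluations.

A "sire" is any animal appearing in the sire column of at least one retained
record.  Because the animal model propagates breeding values through the
pedigree, every sire has an EBV in every analysis, so the three EBV columns
are always complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .animal_model import PosteriorDraws
from .pedigree import UNKNOWN
from .posterior import batch_means_variance, ci_overlap, derived_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "z_test", "spearman", "ebv_regression", "build_ebv_table",
    "ComparisonReport", "compare_analyses",
]


def z_test(mean_a: float, var_a: float, n_a: int,
           mean_b: float, var_b: float, n_b: int) -> tuple[float, float]:
    """Two-sample Z-test on posterior means.

    ``Z = (mean_a - mean_b) / sqrt(var_a/n_a + var_b/n_b)`` with a two-sided
    standard-normal tail probability.  In the heritability comparison the
    variances are those associated with the posterior means and n is the
    retained-draw count.
    """
    if var_a < 0 or var_b < 0 or n_a <= 0 or n_b <= 0:
        raise ValueError("variances must be >= 0 and sample sizes > 0")
    denom = np.sqrt(var_a / n_a + var_b / n_b)
    if denom == 0:
        raise ValueError("zero denominator in Z-test")
    z = (mean_a - mean_b) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on average-tie ranks)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def ebv_regression(y, x) -> tuple[float, float, float]:
    """OLS of one EBV set on another: (intercept, slope, r-squared)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: x has zero variance")
    fit = stats.linregress(x, y)
    return float(fit.intercept), float(fit.slope), float(fit.rvalue ** 2)


def build_ebv_table(records: pd.DataFrame, ped, general: PosteriorDraws,
                    bivariate: PosteriorDraws) -> pd.DataFrame:
    """Per-sire EBVs from the general and class-specific analyses.

    ``records`` is the retained record table (identifies the phenotyped
    animals); sires come from the pedigree's sire column.  Index: sire id;
    columns ``ebv_general``, ``ebv_low``, ``ebv_high``, ``n_offspring``,
    ``positive_in_general``.
    """
    if general.animal_order != bivariate.animal_order:
        raise ValueError("analyses were run on different pedigrees")
    index = {a: i for i, a in enumerate(general.animal_order)}
    sire_of = {a: s for a, s, _ in ped.entries}
    sires_per_record = records["animal"].map(sire_of)
    counts = sires_per_record[sires_per_record != UNKNOWN].value_counts()
    if counts.empty:
        raise ValueError("no retained record has a known sire")
    sires = sorted(counts.index)
    missing = [s for s in sires if s not in index]
    if missing:
        raise ValueError(f"sires absent from pedigree: {missing[:5]}")
    pos = np.array([index[s] for s in sires])
    tab = pd.DataFrame({
        "ebv_general": general.a_mean["general"][pos],
        "ebv_low": bivariate.a_mean["low"][pos],
        "ebv_high": bivariate.a_mean["high"][pos],
        "n_offspring": counts.loc[sires].to_numpy(),
    }, index=pd.Index(sires, name="sire"))
    tab["positive_in_general"] = tab["ebv_general"] > 0
    return tab


@dataclass
class ComparisonReport:
    """Everything the cross-analysis comparison produces."""

    spearman_all: pd.DataFrame
    spearman_positive: pd.DataFrame | None
    regressions: pd.DataFrame
    ztest: pd.DataFrame
    ci_verdicts: pd.DataFrame
    heterogeneity_detected: bool

    def verdict_text(self) -> str:
        flag = "DETECTED" if self.heterogeneity_detected else "not detected"
        lines = [f"Heterogeneity of variance: {flag}"]
        for row in self.ci_verdicts.itertuples(index=False):
            state = "overlap" if row.overlap else "disjoint"
            lines.append(
                f"  {row.parameter}: LOW CI [{row.low_lo:.1f}, {row.low_hi:.1f}]"
                f" vs HIGH CI [{row.high_lo:.1f}, {row.high_hi:.1f}] -> {state}"
            )
        z = self.ztest.iloc[0]
        lines.append(f"  h2 Z-test (MCSE-based): Z = {z['z']:.3f}, p = {z['p']:.4f}")
        return "\n".join(lines)


def _spearman_matrix(tab: pd.DataFrame) -> pd.DataFrame:
    cols = ["ebv_general", "ebv_low", "ebv_high"]
    names = ["general", "low", "high"]
    m = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            m[i, j] = m[j, i] = spearman(tab[cols[i]], tab[cols[j]])
    return pd.DataFrame(m, index=names, columns=names)


def compare_analyses(ebvs: pd.DataFrame,
                     bivariate: PosteriorDraws) -> ComparisonReport:
    """The full cross-analysis comparison.

    Emits Spearman matrices over all sires and over the sires with positive
    general-analysis EBVs, EBV regressions in both orientations and both
    directions, the heritability Z-test between the LOW and HIGH classes
    (default inputs: posterior means, batch-means variances of the means,
    retained-draw counts; a posterior-SD variant is reported alongside
    because the two conventions differ), and CI-overlap verdicts for the
    additive and residual variances.  The heterogeneity flag is raised when
    both variance CIs are disjoint and the Z-test p-value is below 0.05.
    """
    sp_all = _spearman_matrix(ebvs)
    positive = ebvs[ebvs["positive_in_general"]]
    if len(positive) >= 2:
        sp_pos = _spearman_matrix(positive)
    else:
        logger.warning("no sires with positive general EBVs; subset skipped")
        sp_pos = None

    reg_rows = []
    for cls in ("low", "high"):
        for y_name, x_name in ((f"ebv_{cls}", "ebv_general"),
                               ("ebv_general", f"ebv_{cls}")):
            b0, b1, r2 = ebv_regression(ebvs[y_name], ebvs[x_name])
            reg_rows.append({
                "y": y_name.removeprefix("ebv_"),
                "x": x_name.removeprefix("ebv_"),
                "intercept": b0, "slope": b1, "r2": r2,
            })
    regressions = pd.DataFrame(reg_rows)

    h2 = derived_parameters(bivariate.draws)
    n = len(h2)
    lo = h2["h2_low"].to_numpy()
    hi = h2["h2_high"].to_numpy()
    z_rows = []
    # default: variance of the posterior mean (batch means) with the
    # retained-draw count; variant: raw posterior variances without the /n
    # factor, the convention under which a difference of posterior means is
    # compared against the posterior spread itself
    for variant, (vl, vh, nn) in (
        ("mcse", (batch_means_variance(lo) * n, batch_means_variance(hi) * n, n)),
        ("posterior_sd", (float(np.var(lo, ddof=1)),
                          float(np.var(hi, ddof=1)), 1)),
    ):
        z, p = z_test(hi.mean(), vh, nn, lo.mean(), vl, nn)
        z_rows.append({"variant": variant, "z": z, "p": p, "n_draws": n})
    ztest = pd.DataFrame(z_rows)

    ci_rows = []
    all_disjoint = True
    for par in ("sigma2_a", "sigma2_e"):
        lo_ci = np.quantile(bivariate.draws[f"{par}_low"], [0.025, 0.975])
        hi_ci = np.quantile(bivariate.draws[f"{par}_high"], [0.025, 0.975])
        overlap = ci_overlap(tuple(lo_ci), tuple(hi_ci))
        all_disjoint &= not overlap
        ci_rows.append({
            "parameter": par, "low_lo": lo_ci[0], "low_hi": lo_ci[1],
            "high_lo": hi_ci[0], "high_hi": hi_ci[1], "overlap": overlap,
        })
    ci_verdicts = pd.DataFrame(ci_rows)

    detected = all_disjoint and ztest.iloc[0]["p"] < 0.05
    return ComparisonReport(
        spearman_all=sp_all, spearman_positive=sp_pos,
        regressions=regressions, ztest=ztest, ci_verdicts=ci_verdicts,
        heterogeneity_detected=detected,
    )
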