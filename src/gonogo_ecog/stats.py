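"""Cross-patient condition comparisons and age-trend statistics.

No-Go/Correct vs Go/Correct band-power peaks are compared per
(hemisphere, band) stratum with trials pooled across patients.  The group
sizes are unequal by design (the task presents No-Go and Go cues at about
1:6), so the multiple-comparison correction uses the Tukey-Kramer
studentized-range procedure: all (hemisphere x band x condition) cells
form one one-way layout with pooled within-group variance, and each
No-Go-vs-Go pair gets a studentized-range p-value with the family's group
count.  A plain Welch t-test is reported alongside for reference.

Age trends of per-patient ratios (power ratio or PAC ratio vs age) are
quantified with a Spearman rank correlation — the underlying observation
is qualitative (a ratio drifting with age), so a rank statistic at n = 8
is the appropriate quantitative summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

__all__ = ["tukey_kramer_pvalue", "compare_conditions", "age_trend", "AgeTrend"]


def tukey_kramer_pvalue(mean_diff: float, mse: float, n1: int, n2: int,
                        k: int, df: int) -> tuple[float, float]:
    """Studentized-range p-value for one pairwise contrast.

    ``q = |diff| / sqrt(MSE/2 * (1/n1 + 1/n2))`` referred to the
    studentized range with ``k`` groups and ``df`` error degrees of
    freedom (the Kramer extension handles unequal n).  Returns (q, p).
    """
    se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
    q = np.abs(mean_diff) / se
    p = float(sstats.studentized_range.sf(q, k, df))
    return float(q), p


def _ci95(x: np.ndarray) -> tuple[float, float]:
    m = x.mean()
    if x.size < 2:
        return (np.nan, np.nan)
    h = sstats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return (m - h, m + h)


def compare_conditions(peaks: pd.DataFrame,
                       value: str = "value") -> pd.DataFrame:
    """No-Go vs Go comparison per (hemisphere, band) with Tukey-Kramer
    correction across the whole family.

    ``peaks`` is long-form with columns ``hemisphere``, ``band``,
    ``condition`` (go_correct / nogo_correct) and the value column; trials
    are pooled across patients within each stratum.  Strata missing a
    condition (or a hemisphere with no patients) are skipped with a
    warning.
    """
    needed = {"hemisphere", "band", "condition", value}
    if not needed.issubset(peaks.columns):
        raise ValueError(f"peaks must have columns {sorted(needed)}")

    groups = {key: g[value].to_numpy(float)
              for key, g in peaks.groupby(["hemisphere", "band", "condition"])
              if len(g) >= 2}
    if not groups:
        raise ValueError("no groups with >= 2 trials")
    k = len(groups)
    n_total = sum(v.size for v in groups.values())
    df = n_total - k
    mse = sum((v.size - 1) * v.var(ddof=1) for v in groups.values()) / df

    strata = sorted({(h, b) for h, b, _ in groups})
    rows = []
    for hemi, band in strata:
        key_n = (hemi, band, "nogo_correct")
        key_g = (hemi, band, "go_correct")
        if key_n not in groups or key_g not in groups:
            logger.warning("stratum (%s, %s) missing a condition — skipped",
                           hemi, band)
            continue
        x_n, x_g = groups[key_n], groups[key_g]
        diff = x_n.mean() - x_g.mean()
        q, p_corr = tukey_kramer_pvalue(diff, mse, x_n.size, x_g.size, k, df)
        t_res = sstats.ttest_ind(x_n, x_g, equal_var=False)
        ci_n, ci_g = _ci95(x_n), _ci95(x_g)
        rows.append(dict(
            hemisphere=hemi, band=band,
            mean_nogo=x_n.mean(), mean_go=x_g.mean(),
            ci_nogo_low=ci_n[0], ci_nogo_high=ci_n[1],
            ci_go_low=ci_g[0], ci_go_high=ci_g[1],
            n_nogo=x_n.size, n_go=x_g.size,
            t_welch=float(t_res.statistic), p_welch=float(t_res.pvalue),
            q=q, p_tukey=p_corr,
            significant=p_corr < 0.05,
        ))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgeTrend:
    """Spearman rank correlation of a per-patient ratio against age."""
    rho: float
    p: float
    n: int
    direction: str  # 'decreasing', 'increasing' or 'flat'


def age_trend(ages, ratios) -> AgeTrend:
    """Rank-correlate one ratio measure against patient age.

    Requires at least 4 patients with the measure defined; constant
    ratios leave the correlation undefined (NaN, flagged 'flat').
    """
    ages = np.asarray(ages, float)
    ratios = np.asarray(ratios, float)
    ok = np.isfinite(ages) & np.isfinite(ratios)
    ages, ratios = ages[ok], ratios[ok]
    if ages.size < 4:
        raise ValueError(f"need >= 4 patients with the measure defined, "
                         f"got {ages.size}")
    if np.ptp(ratios) == 0 or np.ptp(ages) == 0:
        logger.warning("constant input — trend undefined")
        return AgeTrend(np.nan, np.nan, int(ages.size), "flat")
    rho, p = sstats.spearmanr(ages, ratios)
    direction = "decreasing" if rho < 0 else ("increasing" if rho > 0 else "flat")
    return AgeTrend(float(rho), float(p), int(ages.size), direction)
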