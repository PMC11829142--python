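"""Pooling of published trial summaries and representativeness statistics.

Trial publications typically report enrolled-patient age either as mean (SD)
or as median (IQR).  Median/IQR reports are converted with the Wan et al.
(2014) three-quantile approximation before pooling, so all trials contribute
on the mean/SD scale.  The pooled enrolled population is then compared with
the incident (registry) population by Welch's t-test for age and a 2x2
chi-squared test for sex; deprivation-quintile distributions use a
Cochran-Armitage trend test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SCENARIOS = ("all", "first_line", "no_age_limit", "phase2")


@dataclass(frozen=True)
class PooledSummary:
    """Pooled age/sex statistics of enrolled patients for one subtype."""

    subtype: str
    n_total: int
    pooled_mean_age: float
    pooled_sd_age: float
    pct_male: float
    n_male: int
    n_trials: int


def mean_sd_from_median_iqr(median: float, q1: float, q3: float, n: int):
    """Approximate (mean, sd) from a median/IQR report (Wan et al. 2014, C3).

    mean = (q1 + median + q3) / 3
    sd   = (q3 - q1) / (2 * z((0.75 n - 0.125) / (n + 0.25)))

    The sample-size adjustment in the divisor tends to 2*z(0.75) ~= 1.349 as
    n grows, recovering the familiar IQR/1.35 rule.
    """
    if q3 < q1:
        raise ValueError(f"q3 ({q3}) < q1 ({q1})")
    if not (q1 <= median <= q3):
        raise ValueError("median must lie within [q1, q3]")
    if n < 2:
        raise ValueError("n must be >= 2")
    mean = (q1 + median + q3) / 3.0
    z = stats.norm.ppf((0.75 * n - 0.125) / (n + 0.25))
    sd = (q3 - q1) / (2.0 * z)
    return float(mean), float(sd)


def _as_mean_sd(row: pd.Series):
    """Per-trial (mean, sd), converting a median/IQR report if needed."""
    if pd.notna(row.get("mean_age")) and pd.notna(row.get("sd_age")):
        return float(row["mean_age"]), float(row["sd_age"])
    return mean_sd_from_median_iqr(
        row["median_age"], row["q1_age"], row["q3_age"], int(row["n"])
    )


def pool_trials(summaries: pd.DataFrame, predicate=None) -> PooledSummary:
    """Pool per-trial age/sex summaries into one enrolled-population summary.

    Pooled mean is the n-weighted mean; pooled variance uses the grouped-data
    identity sum[(n_i-1) s_i^2 + n_i (m_i - m)^2] / (sum n_i - 1), which is
    exact when each trial reports the mean/SD of its own raw enrolees.
    """
    df = summaries
    if predicate is not None:
        mask = predicate(df) if callable(predicate) else np.asarray(predicate, dtype=bool)
        df = df.loc[mask]
    if len(df) == 0:
        raise ValueError("no trials left after filtering")
    ms = np.array([_as_mean_sd(row) for _, row in df.iterrows()])
    means, sds = ms[:, 0], ms[:, 1]
    ns = df["n"].to_numpy(dtype=float)
    if np.any(ns < 2):
        raise ValueError("every pooled trial needs n >= 2")
    n_tot = ns.sum()
    grand = float(np.sum(ns * means) / n_tot)
    pooled_var = float(
        np.sum((ns - 1) * sds**2 + ns * (means - grand) ** 2) / (n_tot - 1)
    )
    n_male = int(df["n_male"].sum())
    subtypes = set(df["subtype"])
    subtype = subtypes.pop() if len(subtypes) == 1 else "mixed"
    return PooledSummary(
        subtype=subtype,
        n_total=int(n_tot),
        pooled_mean_age=grand,
        pooled_sd_age=float(np.sqrt(pooled_var)),
        pct_male=100.0 * n_male / n_tot,
        n_male=n_male,
        n_trials=len(df),
    )


def welch_t(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and a
    two-sided p-value.  Vectorised over array inputs.  When both SDs are zero
    and the means are equal the test is degenerate; p = 1 by convention.
    """
    mean1, sd1, n1, mean2, sd2, n2 = (
        np.asarray(v, dtype=float) for v in (mean1, sd1, n1, mean2, sd2, n2)
    )
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("welch_t needs n >= 2 in both groups")
    if np.any(sd1 < 0) or np.any(sd2 < 0):
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    degenerate = se2 == 0
    if np.any(degenerate):
        logger.info("degenerate Welch test (both SDs zero); p=1 where means equal")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (mean1 - mean2) / np.sqrt(np.where(degenerate, 1, se2)))
        df = np.where(
            degenerate,
            n1 + n2 - 2,
            se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)),
        )
    t = np.where(degenerate & (mean1 != mean2), np.copysign(np.inf, mean1 - mean2), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if t.ndim == 0:
        return float(t), float(df), float(p)
    return t, df, p


def chisq_2xk(counts):
    """Pearson chi-squared test on a 2xk table, no continuity correction.

    Returns ``(statistic, df, p)``.  Raises on zero marginal rows/columns
    (expected counts must all be positive).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xk table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column in contingency table")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def chisq_trend(counts, scores=None):
    """Cochran-Armitage test for trend in proportions across ordered columns.

    ``counts`` is 2xk with ordered columns (e.g. deprivation quintiles 1..k);
    ``scores`` defaults to equally spaced 1..k.  Score-test variance (no
    small-sample correction); statistic is chi-squared with 1 df.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xk table")
    k = table.shape[1]
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    n_i = table.sum(axis=0)
    if np.any(n_i == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column in contingency table")
    N = table.sum()
    R = table[0].sum()
    T = float(np.sum(s * table[0]))
    E = R * np.sum(s * n_i) / N
    pbar = R / N
    var = pbar * (1 - pbar) * (np.sum(s**2 * n_i) - np.sum(s * n_i) ** 2 / N)
    if var <= 0:
        raise ValueError("degenerate trend test (single column or empty row)")
    stat = (T - E) ** 2 / var
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


def scenario_filter(scenario: str):
    """Predicate on the trial-summary table for the restriction analyses."""
    if scenario == "all":
        return lambda df: np.ones(len(df), dtype=bool)
    if scenario == "first_line":
        return lambda df: df["first_line"].astype(bool).to_numpy()
    if scenario == "no_age_limit":
        return lambda df: ~df["age_restricted"].astype(bool).to_numpy()
    if scenario == "phase2":
        return lambda df: df["phase"].astype(str).str.upper().isin(["II", "2", "PHASE II"]).to_numpy()
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def representativeness_report(
    summaries: pd.DataFrame,
    patients: pd.DataFrame,
    scenario: str = "all",
    subtypes=None,
) -> pd.DataFrame:
    """Compare pooled enrolled patients with the incident population.

    One row per subtype: mean-age difference (enrolled - population) with a
    Welch p-value, and male-percentage difference with a 2x2 chi-squared
    p-value (both sides treated as independent samples).
    """
    filt = scenario_filter(scenario)
    rows = []
    if subtypes is None:
        subtypes = sorted(set(summaries["subtype"]) & set(patients["subtype"]))
    for sub in subtypes:
        tri = summaries.loc[summaries["subtype"] == sub]
        tri = tri.loc[filt(tri)]
        pop = patients.loc[patients["subtype"] == sub]
        if len(tri) == 0 or len(pop) == 0:
            continue
        pooled = pool_trials(tri)
        pop_age = pop["age"].to_numpy(dtype=float)
        pop_male = int((pop["sex"] == "M").sum())
        t, df, p_age = welch_t(
            pooled.pooled_mean_age, pooled.pooled_sd_age, pooled.n_total,
            pop_age.mean(), pop_age.std(ddof=1), len(pop),
        )
        table = [
            [pooled.n_male, pooled.n_total - pooled.n_male],
            [pop_male, len(pop) - pop_male],
        ]
        _, _, p_male = chisq_2xk(table)
        rows.append(
            {
                "subtype": sub,
                "scenario": scenario,
                "n_trials": pooled.n_trials,
                "n_enrolled": pooled.n_total,
                "n_population": len(pop),
                "enrolled_mean_age": pooled.pooled_mean_age,
                "population_mean_age": float(pop_age.mean()),
                "age_diff": pooled.pooled_mean_age - float(pop_age.mean()),
                "age_p": p_age,
                "enrolled_pct_male": pooled.pct_male,
                "population_pct_male": 100.0 * pop_male / len(pop),
                "male_diff_pp": pooled.pct_male - 100.0 * pop_male / len(pop),
                "male_p": p_male,
            }
        )
    if not rows:
        raise ValueError("no subtype present in both trial summaries and patients")
    return pd.DataFrame(rows)
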