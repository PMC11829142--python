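"""Patient-to-facility assignment, incident populations and group comparison.

A registry patient carries an ordered bundle of organisational records
(decision-to-treat, treatment, diagnosis ...).  The facility of care is
resolved by a configurable priority cascade: the first record source in the
cascade that the patient has wins.  Incident populations are mean annual
diagnosis counts per facility and subtype over a year window; patient
characteristics are then compared between research-active and inactive
facilities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import represent

logger = logging.getLogger(__name__)

#: Default source priority: the explicit decision-to-treat record first, then
#: inferred sources in decreasing reliability.
DEFAULT_CASCADE = ("decision_to_treat", "treatment_record", "diagnosis_record")


def encode_org_records(records) -> str:
    """Serialise [(source_tag, facility_id), ...] for a CSV cell."""
    return "|".join(f"{tag}:{fac}" for tag, fac in records)


def decode_org_records(cell) -> list:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [tuple(part.split(":", 1)) for part in str(cell).split("|")]


def assign_facility(org_records, cascade=DEFAULT_CASCADE):
    """Resolve one patient's facility of care; ``None`` if unassignable."""
    if not cascade:
        raise ValueError("cascade must be non-empty")
    for tag in cascade:
        for rec_tag, fac in org_records:
            if rec_tag == tag:
                return fac
    return None


def assign_facilities(patients: pd.DataFrame, cascade=DEFAULT_CASCADE) -> pd.Series:
    """Vectorised cascade assignment; logs the unassignable count."""
    recs = patients["org_records"]
    if recs.dtype == object and len(recs) and isinstance(recs.iloc[0], str):
        recs = recs.apply(decode_org_records)
    assigned = recs.apply(lambda r: assign_facility(r, cascade))
    n_missing = int(assigned.isna().sum())
    if n_missing:
        logger.info("%d patients unassignable (no record matching cascade %s)",
                    n_missing, list(cascade))
    return assigned.rename("facility_id")


def mean_annual_incidence(
    patients: pd.DataFrame,
    year_range: tuple[int, int],
    cascade=DEFAULT_CASCADE,
) -> pd.DataFrame:
    """Mean annual incident patients per facility and subtype.

    Counts assigned patients diagnosed in the inclusive ``year_range`` and
    divides by the number of years.  Unassignable patients are excluded (and
    counted in the log).  Returns tidy rows
    (facility_id, subtype, patient_count, mean_annual_incidence).
    """
    lo, hi = year_range
    if hi < lo:
        raise ValueError("empty year range")
    n_years = hi - lo + 1
    df = patients.copy()
    df["facility_id"] = assign_facilities(df, cascade)
    df = df.loc[df["facility_id"].notna()]
    df = df.loc[(df["diagnosis_year"] >= lo) & (df["diagnosis_year"] <= hi)]
    counts = (
        df.groupby(["facility_id", "subtype"], as_index=False)
        .size()
        .rename(columns={"size": "patient_count"})
    )
    counts["mean_annual_incidence"] = counts["patient_count"] / n_years
    return counts


def incidence_by_facility(summary: pd.DataFrame, facility_ids=None) -> pd.DataFrame:
    """Collapse a per-subtype incidence summary to totals per facility.

    ``facility_ids`` extends the table with zero-incidence facilities so the
    classification universe covers every care provider.
    """
    tot = (
        summary.groupby("facility_id", as_index=False)["mean_annual_incidence"].sum()
    )
    if facility_ids is not None:
        tot = (
            tot.set_index("facility_id")
            .reindex(pd.Index(facility_ids, name="facility_id"), fill_value=0.0)
            .reset_index()
        )
    return tot


def active_share(summary: pd.DataFrame, labels: pd.Series, subtype: str) -> float:
    """% of the subtype's incident population treated in active facilities."""
    sub = summary.loc[summary["subtype"] == subtype]
    if not set(sub["facility_id"]) <= set(labels.index):
        missing = sorted(set(sub["facility_id"]) - set(labels.index))
        raise ValueError(f"labels missing for facilities {missing}")
    total = sub["mean_annual_incidence"].sum()
    if total == 0:
        raise ValueError(f"zero total incidence for subtype {subtype!r}")
    active = sub.loc[labels.reindex(sub["facility_id"]).to_numpy(dtype=bool),
                     "mean_annual_incidence"].sum()
    return 100.0 * active / total


def compare_groups(
    patients: pd.DataFrame,
    labels: pd.Series,
    subtype: str,
    cascade=DEFAULT_CASCADE,
) -> pd.DataFrame:
    """Characteristics of a subtype's patients by facility activity status.

    Rows: patient count; age mean (SD) with Welch p; % male, % ethnic-majority
    (chi-squared, no continuity correction); % in the two most deprived income
    quintiles, with a Cochran-Armitage trend p over the full quintile
    distribution.
    """
    df = patients.loc[patients["subtype"] == subtype].copy()
    df["facility_id"] = assign_facilities(df, cascade)
    df = df.loc[df["facility_id"].notna()]
    df["active"] = labels.reindex(df["facility_id"]).to_numpy(dtype=bool)
    g_act, g_inact = df.loc[df["active"]], df.loc[~df["active"]]
    if len(g_act) == 0 or len(g_inact) == 0:
        raise ValueError("both activity groups must be non-empty")

    def _binary_row(name, flag_act, flag_inact):
        table = [
            [int(flag_act.sum()), int(len(flag_act) - flag_act.sum())],
            [int(flag_inact.sum()), int(len(flag_inact) - flag_inact.sum())],
        ]
        _, _, p = represent.chisq_2xk(np.asarray(table).T)
        return {
            "characteristic": name,
            "active": 100.0 * flag_act.mean(),
            "inactive": 100.0 * flag_inact.mean(),
            "p_value": p,
        }

    rows = [
        {
            "characteristic": "n_patients",
            "active": float(len(g_act)),
            "inactive": float(len(g_inact)),
            "p_value": np.nan,
        }
    ]
    if len(g_act) < 2 or len(g_inact) < 2:
        raise ValueError("age comparison needs n >= 2 in both groups")
    a1, a2 = g_act["age"].to_numpy(float), g_inact["age"].to_numpy(float)
    _, _, p_age = represent.welch_t(
        a1.mean(), a1.std(ddof=1), len(a1), a2.mean(), a2.std(ddof=1), len(a2)
    )
    rows.append(
        {
            "characteristic": "mean_age",
            "active": float(a1.mean()),
            "inactive": float(a2.mean()),
            "sd_active": float(a1.std(ddof=1)),
            "sd_inactive": float(a2.std(ddof=1)),
            "p_value": p_age,
        }
    )
    rows.append(_binary_row("pct_male", g_act["sex"].eq("M"), g_inact["sex"].eq("M")))
    rows.append(
        _binary_row(
            "pct_ethnic_majority",
            g_act["ethnic_majority"].astype(bool),
            g_inact["ethnic_majority"].astype(bool),
        )
    )
    q = np.arange(1, 6)
    t_act = np.array([(g_act["imd_income_quintile"] == i).sum() for i in q], dtype=float)
    t_inact = np.array([(g_inact["imd_income_quintile"] == i).sum() for i in q], dtype=float)
    keep = (t_act + t_inact) > 0
    _, _, p_trend = represent.chisq_trend(np.vstack([t_act, t_inact])[:, keep], scores=q[keep])
    rows.append(
        {
            "characteristic": "pct_two_most_deprived_quintiles",
            "active": 100.0 * g_act["imd_income_quintile"].isin([1, 2]).mean(),
            "inactive": 100.0 * g_inact["imd_income_quintile"].isin([1, 2]).mean(),
            "p_value": p_trend,
        }
    )
    return pd.DataFrame(rows)
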