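"""Research-activity classification of care facilities.

Five dichotomies are supported:

1. incidence-weighted recruitment strictly above the median across all
   facilities (the primary definition);
2. participation in at least one trial of any subtype;
3-5. participation in at least one DLBCL / HL / FL trial respectively.

Participation counts trials joined even with zero patients recruited, so the
unit of evidence for definitions 2-5 is presence of a (trial, facility) pair
in the recruitment table, not a positive count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Subtypes with their own participation-based definition (defs 3, 4, 5).
SUBTYPE_DEFINITIONS = ("DLBCL", "HL", "FL")


def weighted_recruitment(total_recruited, mean_annual_incidence):
    """Total recruitment divided by mean annual incident patients.

    Vectorised over array inputs.  A facility that recruits patients while
    treating no incident patients is contradictory and raises; a facility with
    neither recruits nor incident patients scores 0 (logged).
    """
    rec = np.asarray(total_recruited, dtype=float)
    inc = np.asarray(mean_annual_incidence, dtype=float)
    if np.any(rec < 0) or np.any(inc < 0):
        raise ValueError("recruitment and incidence must be non-negative")
    bad = (inc == 0) & (rec > 0)
    if np.any(bad):
        raise ValueError(
            "facility recruits patients but has zero incident patients "
            f"(positions {np.flatnonzero(bad).tolist()})"
        )
    both_zero = (inc == 0) & (rec == 0)
    if np.any(both_zero):
        logger.info("%d facilities with zero recruitment and zero incidence -> ratio 0",
                    int(np.sum(both_zero)))
    ratio = np.divide(rec, inc, out=np.zeros_like(rec), where=inc > 0)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def apply_facility_mapping(table: pd.DataFrame, mapping: pd.DataFrame | dict | None,
                           column: str = "facility_id") -> pd.DataFrame:
    """Apply an old-id -> current-id lookup (organisational renames/mergers).

    ``mapping`` is a dict or a two-column DataFrame (old, new); ids absent
    from it pass through unchanged.
    """
    if mapping is None:
        return table
    if isinstance(mapping, pd.DataFrame):
        old, new = mapping.columns[:2]
        mapping = dict(zip(mapping[old].astype(str), mapping[new].astype(str)))
    out = table.copy()
    out[column] = out[column].astype(str).map(lambda f: mapping.get(f, f))
    return out


def build_activity_inputs(
    recruitment: pd.DataFrame,
    trials: pd.DataFrame,
    incidence: pd.DataFrame,
    recruit_years: tuple[int, int] | None = None,
    facility_mapping=None,
) -> pd.DataFrame:
    """Assemble per-facility classification inputs.

    Parameters
    ----------
    recruitment : rows (trial_id, facility_id, year, n_recruited); zero-count
        rows still record participation.
    trials : rows (trial_id, subtype, ...).
    incidence : rows (facility_id, mean_annual_incidence); defines the full
        facility universe (every care provider, recruiting or not).
    recruit_years : inclusive (lo, hi) slice of recruitment years; the
        incidence window is whatever ``incidence`` was computed on — the two
        windows are independent by design.
    facility_mapping : optional rename lookup applied to recruitment ids
        before aggregation.

    Returns
    -------
    DataFrame indexed by facility_id with columns total_recruited,
    participated (frozenset of subtype labels) and mean_annual_incidence.
    """
    rec = apply_facility_mapping(recruitment, facility_mapping)
    if recruit_years is not None:
        lo, hi = recruit_years
        rec = rec.loc[(rec["year"] >= lo) & (rec["year"] <= hi)]
    base = incidence.set_index(incidence["facility_id"].astype(str))["mean_annual_incidence"]

    totals = rec.groupby(rec["facility_id"].astype(str))["n_recruited"].sum()
    joined = rec.merge(trials[["trial_id", "subtype"]], on="trial_id", how="left")
    part = (
        joined.groupby(joined["facility_id"].astype(str))["subtype"]
        .agg(lambda s: frozenset(s.dropna()))
    )
    out = pd.DataFrame(index=base.index)
    out.index.name = "facility_id"
    out["total_recruited"] = totals.reindex(out.index).fillna(0).astype(int)
    out["participated"] = part.reindex(out.index).apply(
        lambda v: v if isinstance(v, frozenset) else frozenset()
    )
    out["mean_annual_incidence"] = base.astype(float)
    return out


def classify_def1(inputs: pd.DataFrame) -> pd.Series:
    """Primary definition: weighted recruitment strictly above the median.

    With all ratios distinct exactly floor(n/2) facilities are active; ties at
    the median are inactive.
    """
    if len(inputs) < 2:
        raise ValueError("definition 1 needs at least two facilities")
    ratio = weighted_recruitment(
        inputs["total_recruited"].to_numpy(), inputs["mean_annual_incidence"].to_numpy()
    )
    med = float(np.median(ratio))
    return pd.Series(ratio > med, index=inputs.index, name="def1")


def classify_participation(inputs: pd.DataFrame, subtype: str = "any") -> pd.Series:
    """Definitions 2-5: participation in >=1 trial (of ``subtype`` if given)."""
    if subtype != "any" and subtype not in SUBTYPE_DEFINITIONS:
        raise ValueError(f"unknown subtype label {subtype!r}; "
                         f"expected 'any' or one of {SUBTYPE_DEFINITIONS}")
    part = inputs["participated"]
    if subtype == "any":
        active = part.apply(lambda s: len(s) > 0)
    else:
        active = part.apply(lambda s: subtype in s)
    return active.rename(f"participation_{subtype}")


def classify_all(inputs: pd.DataFrame) -> pd.DataFrame:
    """Labels under all five definitions plus the weighted-recruitment ratio."""
    out = pd.DataFrame(index=inputs.index)
    out["weighted_recruitment"] = weighted_recruitment(
        inputs["total_recruited"].to_numpy(), inputs["mean_annual_incidence"].to_numpy()
    )
    out["def1"] = classify_def1(inputs)
    out["def2"] = classify_participation(inputs, "any")
    for k, sub in enumerate(SUBTYPE_DEFINITIONS, start=3):
        out[f"def{k}"] = classify_participation(inputs, sub)
    return out
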