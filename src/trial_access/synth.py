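"""Synthetic geographies, facilities, trials, recruitment and registry patients.

Every downstream stage of the pipeline gets a recovery test against known
ground truth, so the generator plants:

* a true positive distance effect of rurality (facilities sit in urban
  clusters; rural areas are placed uniformly over the bounding box);
* a linear ecological distance response with configurable coefficients
  (:func:`ecological_distance`), for regression parameter-recovery;
* a known research-active facility subset carrying all recruitment;
* trial-vs-population representativeness gaps (enrolees younger by
  ``repr_age_shift`` years, male share higher by ``repr_male_shift`` points);
* a skewed per-facility recruitment distribution via gamma frailty.

One integer seed feeds a fixed per-table substream, so each table is
bit-identical across runs and regenerable in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import geo
from .catchment import encode_org_records  # noqa: F401  (re-exported for CSV IO)

logger = logging.getLogger(__name__)

#: Planted ecological coefficients (km per unit of each area characteristic).
DEFAULT_BETA = {
    "mean_age": 0.4,
    "pct_male": 0.386,
    "pct_ethnic_majority": 0.123,
    "imd_decile": -0.216,
    "rural": 8.0,
    "coastal_border": 2.75,
}

#: Per-subtype (mean age, SD age, male probability) of the incident population.
SUBTYPE_PARAMS = {
    "DLBCL": (69.0, 14.0, 0.55),
    "HL": (48.0, 20.0, 0.56),
    "FL": (65.0, 13.0, 0.48),
    "OTHER": (64.0, 15.0, 0.52),
}

SUBTYPE_PROBS = {"DLBCL": 0.45, "HL": 0.20, "FL": 0.25, "OTHER": 0.10}

_AGE_BOUNDS = (0.0, 110.0)

_STREAMS = {
    "geography": 11,
    "trials": 13,
    "recruitment": 17,
    "patients": 19,
    "summaries": 23,
    "response": 29,
}


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters of one synthetic study population."""

    n_areas: int = 500
    n_facilities: int = 24
    #: (lon_min, lat_min, lon_max, lat_max), decimal degrees.
    bbox: tuple = (-5.8, 50.0, 1.7, 55.8)
    seed: int = 0
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept: float = -32.0
    noise_sd: float = 5.0
    frac_active: float = 0.5
    recruit_shape: float = 1.0
    repr_age_shift: float = 10.0
    repr_male_shift: float = 3.0
    years: tuple = (2014, 2021)
    n_trials: int = 12
    n_patients: int = 8000
    rural_frac: float = 0.3
    coastal_frac: float = 0.25
    urban_spread_deg: float = 0.08
    trial_n_range: tuple = (40, 200)

    def __post_init__(self):
        lon0, lat0, lon1, lat1 = self.bbox
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError("degenerate bbox: zero width or height")
        if not self.n_areas >= self.n_facilities >= 2:
            raise ValueError("need n_areas >= n_facilities >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.frac_active < 1:
            raise ValueError("frac_active must be in (0, 1)")
        if self.recruit_shape <= 0:
            raise ValueError("recruit_shape must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")


def _rng(cfg: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


def _truncnorm(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_geography(cfg: SynthConfig):
    """Areas with sociodemographics and facilities placed in urban clusters.

    Facilities double as the urban cluster centres: urban areas scatter
    normally (SD ``urban_spread_deg`` degrees) around a random facility while
    rural areas are uniform over the box, so rurality has a true positive
    effect on nearest-facility distance by construction.
    """
    rng = _rng(cfg, "geography")
    lon0, lat0, lon1, lat1 = cfg.bbox
    w, h = lon1 - lon0, lat1 - lat0

    fac_lon = rng.uniform(lon0 + 0.1 * w, lon1 - 0.1 * w, cfg.n_facilities)
    fac_lat = rng.uniform(lat0 + 0.1 * h, lat1 - 0.1 * h, cfg.n_facilities)
    facilities = pd.DataFrame(
        {
            "facility_id": [f"F{i:03d}" for i in range(cfg.n_facilities)],
            "lon": fac_lon,
            "lat": fac_lat,
            "provides_care": True,
        }
    )

    n = cfg.n_areas
    rural = rng.random(n) < cfg.rural_frac
    coastal = rng.random(n) < cfg.coastal_frac
    cluster = rng.integers(0, cfg.n_facilities, n)
    lon = np.where(
        rural,
        rng.uniform(lon0, lon1, n),
        np.clip(fac_lon[cluster] + rng.normal(0, cfg.urban_spread_deg, n), lon0, lon1),
    )
    lat = np.where(
        rural,
        rng.uniform(lat0, lat1, n),
        np.clip(fac_lat[cluster] + rng.normal(0, cfg.urban_spread_deg, n), lat0, lat1),
    )
    areas = pd.DataFrame(
        {
            "area_id": [f"A{i:05d}" for i in range(n)],
            "lon": lon,
            "lat": lat,
            "population": rng.integers(1000, 3001, n),
            "mean_age": _truncnorm(rng, 25, 60, 41.0, 4.0, n),
            "pct_male": np.clip(rng.normal(49.5, 1.5, n), 0, 100),
            "pct_ethnic_majority": np.clip(rng.normal(85.0, 8.0, n), 0, 100),
            "imd_decile": rng.integers(1, 11, n),
            "rural": rural,
            "coastal_border": coastal,
        }
    )
    return areas, facilities


def ecological_distance(cfg: SynthConfig, areas: pd.DataFrame, rng=None) -> np.ndarray:
    """Planted linear distance response: intercept + X beta + N(0, noise_sd).

    This is the regression ground truth for parameter recovery; it is not
    derived from the geometry (geometric nearest distances are available via
    :func:`trial_access.geo.access_table`).  Values are left unclipped so
    classical OLS inference on the planted coefficients is exact.
    """
    if rng is None:
        rng = _rng(cfg, "response")
    X = np.column_stack(
        [areas[c].to_numpy(dtype=float) for c in DEFAULT_BETA]
    )
    beta = np.array([cfg.beta[c] for c in DEFAULT_BETA], dtype=float)
    return cfg.intercept + X @ beta + rng.normal(0.0, cfg.noise_sd, len(areas))


def generate_trials(cfg: SynthConfig) -> pd.DataFrame:
    """Trial metadata: subtype, phase, line, age restriction, open/close years."""
    rng = _rng(cfg, "trials")
    subs = list(SUBTYPE_PARAMS)
    rows = []
    for j in range(cfg.n_trials):
        open_year = int(rng.integers(cfg.years[0], cfg.years[1] + 1))
        close_year = int(min(open_year + rng.integers(1, 5), cfg.years[1]))
        rows.append(
            {
                "trial_id": f"T{j:03d}",
                "subtype": subs[j % len(subs)],
                "phase": "II" if rng.random() < 0.5 else "III",
                "first_line": bool(rng.random() < 0.6),
                "age_restricted": bool(rng.random() < 0.3),
                "open_year": open_year,
                "close_year": close_year,
            }
        )
    return pd.DataFrame(rows)


class RecruitmentResult(NamedTuple):
    trials: pd.DataFrame
    recruitment: pd.DataFrame
    active_ids: tuple
    participants_by_subtype: dict


def generate_recruitment(cfg: SynthConfig, facilities: pd.DataFrame,
                         trials: pd.DataFrame | None = None,
                         base_rate: float = 2.0) -> RecruitmentResult:
    """Per-(trial, facility, year) recruitment with facility gamma frailty.

    A planted subset of ``round(frac_active * n_facilities)`` facilities
    carries all recruitment.  Each active facility joins one to three trials
    and its annual counts are Poisson with rate ``base_rate * u_f`` where
    ``u_f ~ Gamma(recruit_shape, 1/recruit_shape)`` (mean 1); small
    ``recruit_shape`` gives the skewed between-facility distribution of real
    recruitment, large values make facilities exchangeable.  Every active
    facility recruits at least one patient overall so the planted labels are
    exactly recoverable.  Zero-count rows are kept: they record participation.
    """
    if len(facilities) == 0:
        raise ValueError("facilities table is empty")
    rng = _rng(cfg, "recruitment")
    if trials is None:
        trials = generate_trials(cfg)
    fac_ids = facilities["facility_id"].astype(str).to_numpy()
    n_active = max(1, int(round(cfg.frac_active * len(fac_ids))))
    active_ids = tuple(sorted(rng.choice(fac_ids, n_active, replace=False)))
    frailty = rng.gamma(cfg.recruit_shape, 1.0 / cfg.recruit_shape, n_active)

    rows = []
    participants: dict[str, set] = {s: set() for s in SUBTYPE_PARAMS}
    for f_idx, fac in enumerate(active_ids):
        k = int(rng.integers(1, 4))
        joined = rng.choice(len(trials), size=min(k, len(trials)), replace=False)
        for t_idx in joined:
            tri = trials.iloc[int(t_idx)]
            participants[tri["subtype"]].add(fac)
            for year in range(int(tri["open_year"]), int(tri["close_year"]) + 1):
                rows.append(
                    {
                        "trial_id": tri["trial_id"],
                        "facility_id": fac,
                        "year": year,
                        "n_recruited": int(rng.poisson(base_rate * frailty[f_idx])),
                    }
                )
    rec = pd.DataFrame(rows)
    totals = rec.groupby("facility_id")["n_recruited"].sum()
    for fac in active_ids:  # guarantee recoverability of the planted set
        if totals.get(fac, 0) == 0:
            first = rec.index[rec["facility_id"] == fac][0]
            rec.loc[first, "n_recruited"] = 1
    return RecruitmentResult(trials, rec, active_ids,
                             {s: frozenset(v) for s, v in participants.items()})


def generate_patients(cfg: SynthConfig, areas: pd.DataFrame,
                      facilities: pd.DataFrame) -> pd.DataFrame:
    """Registry patients with home areas, ages, sex and organisational records.

    Home area is drawn proportional to area population; the true facility of
    care is the nearest facility to the home centroid.  Each patient carries
    one to three candidate organisational records whose highest-priority
    entry always points at the true facility, so the assignment cascade is
    exactly recoverable; ~2% of patients carry no records (unassignable).
    """
    if len(areas) == 0 or len(facilities) == 0:
        raise ValueError("areas and facilities must be non-empty")
    rng = _rng(cfg, "patients")
    n = cfg.n_patients
    pop = areas["population"].to_numpy(dtype=float)
    home = rng.choice(len(areas), size=n, p=pop / pop.sum())

    subs = list(SUBTYPE_PROBS)
    subtype = rng.choice(subs, size=n, p=[SUBTYPE_PROBS[s] for s in subs])
    age = np.empty(n)
    male = np.empty(n, dtype=bool)
    for s in subs:
        mask = subtype == s
        mu, sd, p_male = SUBTYPE_PARAMS[s]
        age[mask] = _truncnorm(rng, *_AGE_BOUNDS, mu, sd, int(mask.sum()))
        male[mask] = rng.random(int(mask.sum())) < p_male

    fac_sorted = facilities.sort_values("facility_id", kind="mergesort").reset_index(drop=True)
    near_ids, _ = geo._nearest_block(
        areas["lon"].to_numpy(), areas["lat"].to_numpy(), fac_sorted
    )
    true_fac = near_ids[home]
    fac_ids = facilities["facility_id"].astype(str).to_numpy()

    u = rng.random(n)
    decoy = rng.random(n)
    records = []
    expected = []
    for i in range(n):
        if u[i] >= 0.98:
            records.append([])
            expected.append(None)
            continue
        if u[i] < 0.85:
            recs = [("decision_to_treat", true_fac[i])]
            lower = ["treatment_record", "diagnosis_record"]
        elif u[i] < 0.93:
            recs = [("treatment_record", true_fac[i])]
            lower = ["diagnosis_record"]
        else:
            recs = [("diagnosis_record", true_fac[i])]
            lower = []
        if lower and decoy[i] < 0.3:  # lower-priority decoy pointing elsewhere
            recs.append((lower[0], str(rng.choice(fac_ids))))
            if len(lower) > 1 and decoy[i] < 0.1:
                recs.append((lower[1], str(rng.choice(fac_ids))))
        records.append(recs)
        expected.append(true_fac[i])

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "subtype": subtype,
            "diagnosis_year": rng.integers(cfg.years[0], cfg.years[1] + 1, n),
            "age": age,
            "sex": np.where(male, "M", "F"),
            "ethnic_majority": rng.random(n) < 0.87,
            "imd_income_quintile": ((areas["imd_decile"].to_numpy()[home] + 1) // 2),
            "home_area_id": areas["area_id"].to_numpy()[home],
            "expected_facility_id": expected,
            "org_records": records,
        }
    )


def simulate_enrolees(rng, n, mean_age, sd_age, p_male,
                      age_shift=0.0, male_shift_pp=0.0):
    """Raw enrolee ages and male count for one trial, with planted shifts."""
    ages = _truncnorm(rng, *_AGE_BOUNDS, mean_age - age_shift, sd_age, n)
    p = float(np.clip(p_male + male_shift_pp / 100.0, 0.0, 1.0))
    n_male = int(rng.binomial(n, p))
    return ages, n_male


def generate_trial_summaries(cfg: SynthConfig, patients: pd.DataFrame,
                             trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Published-style per-trial age/sex summaries of simulated enrolees.

    Enrolee ages are drawn from the subtype's age distribution shifted down
    by ``repr_age_shift`` years; the male probability is raised by
    ``repr_male_shift`` percentage points.  Trials alternate between
    reporting mean/SD and median/IQR (computed from the simulated enrolee
    sample), so the conversion path is exercised.  Trials drawing fewer than
    two enrolees are excluded and logged.
    """
    if len(patients) == 0:
        raise ValueError("patients table is empty")
    rng = _rng(cfg, "summaries")
    if trials is None:
        trials = generate_trials(cfg)
    lo, hi = cfg.trial_n_range
    rows = []
    for j, tri in trials.reset_index(drop=True).iterrows():
        sub = tri["subtype"]
        if sub not in SUBTYPE_PARAMS:
            continue
        mu, sd, p_male = SUBTYPE_PARAMS[sub]
        n_j = int(rng.integers(lo, hi + 1))
        if n_j < 2:
            logger.info("trial %s excluded: %d enrolee(s)", tri["trial_id"], n_j)
            continue
        ages, n_male = simulate_enrolees(
            rng, n_j, mu, sd, p_male, cfg.repr_age_shift, cfg.repr_male_shift
        )
        row = {
            "trial_id": tri["trial_id"],
            "subtype": sub,
            "n": n_j,
            "mean_age": np.nan,
            "sd_age": np.nan,
            "median_age": np.nan,
            "q1_age": np.nan,
            "q3_age": np.nan,
            "n_male": n_male,
            "first_line": tri.get("first_line", True),
            "age_restricted": tri.get("age_restricted", False),
            "phase": tri.get("phase", "II"),
        }
        if j % 2 == 0:
            row["mean_age"] = float(np.mean(ages))
            row["sd_age"] = float(np.std(ages, ddof=1))
        else:
            q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
            row.update(median_age=float(med), q1_age=float(q1), q3_age=float(q3))
        rows.append(row)
    return pd.DataFrame(rows)


def generate_all(cfg: SynthConfig) -> dict:
    """Run the full generator; returns tables plus planted ground truth."""
    areas, facilities = generate_geography(cfg)
    trials, recruitment, active_ids, by_subtype = generate_recruitment(cfg, facilities)
    patients = generate_patients(cfg, areas, facilities)
    summaries = generate_trial_summaries(cfg, patients, trials)
    return {
        "areas": areas,
        "facilities": facilities,
        "trials": trials,
        "recruitment": recruitment,
        "patients": patients,
        "trial_summaries": summaries,
        "active_ids": active_ids,
        "participants_by_subtype": by_subtype,
    }


def write_tables(tables: dict, out_dir) -> None:
    """Write the generated tables as UTF-8 CSVs with one header row."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name in ("areas", "facilities", "trials", "recruitment",
                 "patients", "trial_summaries"):
        df = tables[name]
        if name == "patients":
            df = df.copy()
            df["org_records"] = df["org_records"].apply(encode_org_records)
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
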