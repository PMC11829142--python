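"""Generator contracts: determinism, planted effects, calibration and power."""

import math

import numpy as np
import pandas as pd
import pytest

from trial_access import represent
from trial_access.geo import EARTH_RADIUS_KM
from trial_access.synth import (
    SUBTYPE_PARAMS,
    SynthConfig,
    generate_all,
    generate_geography,
    generate_patients,
    generate_recruitment,
    generate_trial_summaries,
    simulate_enrolees,
)


def brute_mean_nearest_km(areas, facilities):
    """Independent oracle: mean over per-area brute-force nearest distances."""
    total = 0.0
    for a in areas.itertuples():
        best = math.inf
        for f in facilities.itertuples():
            p1, p2 = math.radians(a.lat), math.radians(f.lat)
            dl = math.radians(f.lon - a.lon)
            c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
            best = min(best, EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c))))
        total += best
    return total / len(areas)


class TestConfig:
    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError, match="bbox"):
            SynthConfig(bbox=(0.0, 50.0, 0.0, 55.0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_areas=5, n_facilities=10)
        with pytest.raises(ValueError):
            SynthConfig(frac_active=1.0)
        with pytest.raises(ValueError):
            SynthConfig(noise_sd=-1.0)


class TestDeterminism:
    def test_fixed_seed_reproduces_all_tables(self, cfg, tables):
        again = generate_all(cfg)
        for name in ("areas", "facilities", "trials", "recruitment",
                     "patients", "trial_summaries"):
            pd.testing.assert_frame_equal(tables[name], again[name])
        assert tables["active_ids"] == again["active_ids"]

    def test_tables_regenerable_in_isolation(self, cfg, tables):
        """Per-table substreams: geography alone matches the full run."""
        areas, facilities = generate_geography(cfg)
        pd.testing.assert_frame_equal(areas, tables["areas"])
        pd.testing.assert_frame_equal(facilities, tables["facilities"])


class TestGeography:
    def test_row_counts_and_bbox_containment(self, cfg, tables):
        areas, facilities = tables["areas"], tables["facilities"]
        assert len(areas) == cfg.n_areas and len(facilities) == cfg.n_facilities
        lon0, lat0, lon1, lat1 = cfg.bbox
        for df in (areas, facilities):
            assert df["lon"].between(lon0, lon1).all()
            assert df["lat"].between(lat0, lat1).all()

    def test_equal_area_and_facility_counts_allowed(self):
        areas, facilities = generate_geography(
            SynthConfig(n_areas=10, n_facilities=10, seed=5)
        )
        assert len(areas) == len(facilities) == 10

    def test_all_rural_run_is_farther_than_all_urban(self):
        """Rurality has a true positive distance effect by construction."""
        rural_cfg = SynthConfig(seed=77, n_areas=150, n_facilities=8, rural_frac=0.999)
        urban_cfg = SynthConfig(seed=77, n_areas=150, n_facilities=8, rural_frac=0.001)
        a_r, f_r = generate_geography(rural_cfg)
        a_u, f_u = generate_geography(urban_cfg)
        pd.testing.assert_frame_equal(f_r, f_u)  # same seed, same facilities
        assert brute_mean_nearest_km(a_r, f_r) > brute_mean_nearest_km(a_u, f_u)

    def test_generated_ranges_valid(self, tables):
        areas = tables["areas"]
        assert areas["pct_male"].between(0, 100).all()
        assert areas["pct_ethnic_majority"].between(0, 100).all()
        assert areas["imd_decile"].between(1, 10).all()
        assert (areas["population"] > 0).all()


class TestRecruitment:
    def test_counts_conserved_in_marginals(self, tables):
        rec = tables["recruitment"]
        assert (rec["n_recruited"] >= 0).all()
        assert rec.groupby("facility_id")["n_recruited"].sum().sum() == rec["n_recruited"].sum()

    def test_only_planted_facilities_recruit(self, tables):
        rec = tables["recruitment"]
        assert set(rec["facility_id"]) <= set(tables["active_ids"])
        totals = rec.groupby("facility_id")["n_recruited"].sum()
        assert (totals.reindex(tables["active_ids"]) > 0).all()

    def test_large_frailty_shape_makes_facilities_exchangeable(self):
        """As recruit_shape grows the frailty degenerates to 1: per-trial-year

        rates equalise across facilities, so the between-facility spread of
        mean counts per trial-year shrinks relative to a skewed run."""
        def cv_of_rates(shape, seed=31):
            cfg = SynthConfig(seed=seed, n_areas=40, n_facilities=20,
                              recruit_shape=shape, n_trials=30)
            _, facilities = generate_geography(cfg)
            res = generate_recruitment(cfg, facilities)
            per = res.recruitment.groupby("facility_id")["n_recruited"].mean()
            return per.std() / per.mean()

        assert cv_of_rates(1e6) < cv_of_rates(0.15)

    def test_empty_facilities_rejected(self, cfg):
        with pytest.raises(ValueError):
            generate_recruitment(cfg, pd.DataFrame(columns=["facility_id"]))


class TestPatients:
    def test_subtype_mean_age_within_three_se(self):
        """DLBCL-analog empirical mean within 3 SE of the configured 69 at n=10k."""
        cfg = SynthConfig(seed=501, n_areas=100, n_facilities=6, n_patients=10_000)
        areas, facilities = generate_geography(cfg)
        patients = generate_patients(cfg, areas, facilities)
        sub = patients.loc[patients["subtype"] == "DLBCL", "age"]
        mu, sd, _ = SUBTYPE_PARAMS["DLBCL"]
        assert abs(sub.mean() - mu) < 3 * sd / np.sqrt(len(sub))

    def test_primary_record_holders_assigned_to_primary(self, tables):
        patients = tables["patients"]
        primary = patients["org_records"].apply(
            lambda r: len(r) > 0 and r[0][0] == "decision_to_treat"
        )
        from trial_access.catchment import assign_facilities

        assigned = assign_facilities(patients[primary])
        first = patients.loc[primary, "org_records"].apply(lambda r: r[0][1])
        assert (assigned == first).all()

    def test_quintiles_and_flags_valid(self, tables):
        patients = tables["patients"]
        assert patients["imd_income_quintile"].between(1, 5).all()
        assert patients["sex"].isin(["M", "F"]).all()
        assert (patients["age"] >= 0).all()
        assert patients["diagnosis_year"].between(2014, 2021).all()


class TestTrialSummaries:
    def test_tiny_trials_excluded_and_logged(self, caplog):
        cfg = SynthConfig(seed=601, n_areas=50, n_facilities=4, n_patients=500,
                          trial_n_range=(1, 2), n_trials=10)
        areas, facilities = generate_geography(cfg)
        patients = generate_patients(cfg, areas, facilities)
        with caplog.at_level("INFO", logger="trial_access.synth"):
            summaries = generate_trial_summaries(cfg, patients)
        assert len(summaries) < 10
        assert (summaries["n"] >= 2).all()
        assert "excluded" in caplog.text

    def test_both_report_styles_present(self, tables):
        s = tables["trial_summaries"]
        assert s["mean_age"].notna().any()
        assert s["median_age"].notna().any()
        ok = s["mean_age"].notna() ^ s["median_age"].notna()
        assert ok.all()
        assert (s["n_male"] <= s["n"]).all()

    def test_converted_mean_close_to_sample_mean_typically(self):
        """Median/IQR conversion of a normal n=200 enrolee sample: the median
        absolute deviation from the sample mean over replicates is < 0.5 y."""
        rng = np.random.default_rng(41)
        errs = []
        for _ in range(51):
            ages, _ = simulate_enrolees(rng, 200, 65.0, 12.0, 0.5)
            q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
            m, _ = represent.mean_sd_from_median_iqr(med, q1, q3, 200)
            errs.append(abs(m - ages.mean()))
        assert np.median(errs) < 0.5


def _pooled_vs_population_p(rng, age_shift, n_trials=5, n_per=60, n_pop=800,
                            mu=69.0, sd=14.0):
    """One replicate of the pooled-age representativeness test."""
    rows = []
    for j in range(n_trials):
        ages = rng.normal(mu - age_shift, sd, n_per)
        row = {"trial_id": f"T{j}", "subtype": "DLBCL", "n": n_per,
               "mean_age": np.nan, "sd_age": np.nan, "median_age": np.nan,
               "q1_age": np.nan, "q3_age": np.nan, "n_male": 0,
               "first_line": True, "age_restricted": False, "phase": "II"}
        if j % 2 == 0:
            row["mean_age"], row["sd_age"] = ages.mean(), ages.std(ddof=1)
        else:
            q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
            row.update(median_age=med, q1_age=q1, q3_age=q3)
        rows.append(row)
    pooled = represent.pool_trials(pd.DataFrame(rows))
    pop = rng.normal(mu, sd, n_pop)
    _, _, p = represent.welch_t(
        pooled.pooled_mean_age, pooled.pooled_sd_age, pooled.n_total,
        pop.mean(), pop.std(ddof=1), n_pop,
    )
    return p, pooled


class TestPlantedRepresentativenessEffects:
    def test_null_rejection_rate_near_nominal_alpha(self):
        """No planted shift: the pooled age test rejects at ~5% (500 reps)."""
        rng = np.random.default_rng(71)
        rejections = sum(_pooled_vs_population_p(rng, 0.0)[0] < 0.05 for _ in range(500))
        assert 0.03 <= rejections / 500 <= 0.075

    def test_planted_ten_year_gap_detected_with_high_power(self):
        """10-year shift, 5 trials of n=60: power > 0.9 over 200 replicates."""
        rng = np.random.default_rng(72)
        rejections = sum(_pooled_vs_population_p(rng, 10.0)[0] < 0.05 for _ in range(200))
        assert rejections / 200 > 0.9

    def test_planted_male_excess_significant_in_most_replicates(self):
        """+5pp male share, 2000 enrolled vs 12000 population: significant and
        positive in >95% of replicates."""
        rng = np.random.default_rng(73)
        hits = 0
        for _ in range(200):
            n_e, n_p = 2000, 12000
            m_e = rng.binomial(n_e, 0.60)
            m_p = rng.binomial(n_p, 0.55)
            _, _, p = represent.chisq_2xk([[m_e, n_e - m_e], [m_p, n_p - m_p]])
            hits += (p < 0.05) and (m_e / n_e > m_p / n_p)
        assert hits / 200 > 0.95

    def test_end_to_end_gap_close_to_planted_value(self):
        """Full generator with a 10-year planted gap reports ~-10 years."""
        cfg = SynthConfig(seed=88, n_areas=150, n_facilities=8, n_patients=12_000,
                          n_trials=40, trial_n_range=(150, 200), repr_age_shift=10.0)
        t = generate_all(cfg)
        rep = represent.representativeness_report(t["trial_summaries"], t["patients"])
        d = rep.set_index("subtype").loc["DLBCL", "age_diff"]
        assert d == pytest.approx(-10.0, abs=1.0)
        assert (rep["male_diff_pp"] > 0).all()
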