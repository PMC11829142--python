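# Methods

## Problem and model

The package quantifies two linked inequities in a clinical-trial site
network: (i) geographic — how far people in each small area live from a
facility that actually recruits to trials, and how that burden co-varies with
the area's sociodemographics; and (ii) representational — how the age and sex
of trial enrolees compare with the incident patient population. The units are
small census areas with population-weighted centroids (origin points of
travel), and care facilities with point coordinates that both treat incident
patients and may recruit to trials.

### Research-activity definitions

A facility's *weighted recruitment* is its total trial recruitment over a
configurable year window divided by its mean annual incident patient count
(computed over an independent, typically shorter, window; the two windows are
deliberately decoupled). The primary dichotomy labels a facility active iff
its weighted recruitment is **strictly greater than the median** across all
care facilities; ties at the median are inactive, so with an odd number of
distinct values the median facility itself is inactive and with all values
distinct exactly ⌊n/2⌋ are active. This strict reading is what makes a
universe of 127 facilities — 80 with distinct positive ratios and 47 with
zero — yield 63 active: the median is the 17th-smallest positive ratio, and
the 63 ratios above it are active. Secondary definitions are set-membership
on participation (any subtype; DLBCL; HL; FL), where joining a trial with
zero recruits still counts as participation. A facility that recruits
patients while treating no incident patients is surfaced as an error, not
silently imputed.

### Geographic access

Distances are great-circle kilometres by the haversine formula on a sphere of
radius 6371.0088 km (IUGG mean; the choice of radius is a documented
constant, not an empirical quantity). Coordinates are WGS84 decimal degrees;
no projected-CRS computation is performed. For each area we record the
nearest care facility, the nearest research-active facility, and the *excess
distance* `d_active − d_care` when the nearest care facility is inactive
(zero otherwise); exact distance ties in nearest-facility search break to the
lexicographically smallest facility id, making results order-independent.
Travel time is a provider contract so a road-routing backend can be plugged
in; the bundled default is a constant-speed model (50 km/h over the
great-circle distance) and its output is labelled with the provider name in
all summaries. Provider failures propagate with route context rather than
being imputed.

### Patient assignment and incident populations

A registry patient's facility of care is resolved by a priority cascade over
their organisational records; the default order is
`decision_to_treat → treatment_record → diagnosis_record`, configurable
because record systems differ. Patients with no matching record are excluded
from incidence with a logged count. Mean annual incidence per facility and
subtype is assigned-patient count in the window divided by the number of
years; shares of the incident population in active vs inactive facilities sum
to 100 by construction. Group comparisons report n, mean (SD) age with a
Welch p-value, % male and % majority-ethnicity with 2×2 chi-squared p-values,
and % in the two most deprived income quintiles with a Cochran–Armitage trend
p over the full quintile distribution. Patient-level deprivation uses the
income-domain quintile; area-level regression uses the overall deprivation
decile — two distinct variables by design.

### Representativeness

Per-trial published summaries are pooled per subtype: n-weighted mean and the
grouped-data variance identity `Σ[(nᵢ−1)sᵢ² + nᵢ(x̄ᵢ−x̄)²]/(Σnᵢ−1)`, which is
exact when each trial reports statistics of its own raw enrolees. Median/IQR
reports are first converted by the Wan et al. (2014) approximation:
`mean = (q1+m+q3)/3` and `sd = (q3−q1)/(2·z((0.75n−0.125)/(n+0.25)))`, whose
divisor tends to 1.349 (the IQR/1.35 rule) as n→∞. The pooled enrolled
population is compared with the registry population by Welch's t-test (both
sides treated as independent samples summarised by mean/SD/n) and by a 2×2
chi-squared test for sex — the population is an independent sample, not a
fixed known proportion. Chi-squared tests use no continuity correction,
matching large-sample practice at registry scale. Restriction scenarios
(first-line trials, trials without age-limiting eligibility, phase II trials)
are metadata predicates on the trial summary table; the population comparator
keeps the full diagnosis window in all scenarios (restricting it to
trial-open years is possible upstream by filtering the patient table).

### Ecological regression

Unweighted OLS with intercept of area distance (km) on six regressors — mean
age (years), % male, % majority ethnicity, deprivation decile (one linear
term, 1 = most deprived), rural flag, coastal/border flag — with classical
standard errors and t-distribution p-values. Percentages and the decile enter
untransformed. A `weights=` option switches to population-weighted WLS; a
travel-time response can be fitted through the same interface. Rank-deficient
designs raise, naming the collinear columns found via QR.

## Synthetic-data generator

The generator emulates the input tables end to end with known ground truth:

* **Geography.** Facilities are uniform in the interior of the bounding box
  and double as urban cluster centres; urban areas scatter N(0, 0.08°) around
  a random facility while rural areas (default 30%) are uniform over the box,
  so rurality has a true positive nearest-distance effect by construction.
  Area covariates: mean age ~ Normal(41, 4) truncated to [25, 60]; % male ~
  Normal(49.5, 1.5); % majority ethnicity ~ Normal(85, 8), both clipped to
  [0, 100]; deprivation decile uniform on 1..10; population uniform on
  1000–3000 (the small-area design range); coastal flag Bernoulli(0.25).
* **Planted regression response.** `ecological_distance` draws
  `β₀ + Xβ + N(0, noise_sd)` with default β = (0.4, 0.386, 0.123, −0.216,
  8.0, 2.75) km per unit and noise 5 km — effect sizes of the magnitude an
  England-scale analysis reports, dominated by the rural term. The response
  is left unclipped so classical OLS inference on the planted coefficients is
  exact; it is the regression ground truth, distinct from the geometric
  nearest distances (which embed the rural placement effect instead).
* **Recruitment.** A planted subset (default half) of facilities carries all
  recruitment. Each active facility joins 1–3 trials; annual counts are
  Poisson with rate 2·u_f where u_f ~ Gamma(shape, 1/shape) is a mean-1
  facility frailty — small shape gives the heavy between-facility skew seen
  in real recruitment (most facilities recruit few, a handful recruit many),
  large shape makes facilities exchangeable. The frailty model is a stand-in
  chosen for its skewness, not an inference about any real network. Zero
  count rows are kept (participation without recruits), and each active
  facility recruits at least one patient overall so planted labels are
  exactly recoverable.
* **Patients.** Home area ∝ area population; subtype mix DLBCL/HL/FL/other =
  0.45/0.20/0.25/0.10; ages truncated-normal on [0, 110] with subtype means
  (SDs) 69 (14), 48 (20), 65 (13), 64 (15); male probabilities 0.55, 0.56,
  0.48, 0.52. The income-deprivation quintile is inherited from the home
  area's decile. The true facility of care is the nearest facility to the
  home centroid; each patient carries 1–3 organisational records whose
  highest-priority entry always points at the true facility (lower-priority
  decoys point elsewhere), and ~2% carry none.
* **Trial summaries.** Enrolee ages are drawn from the subtype's (truncated
  normal) age distribution shifted down by `repr_age_shift` (default 10
  years, the order of the largest published gaps) and the male probability is
  raised by `repr_male_shift` (default 3 points, mid-range of published
  gaps). Enrolees are drawn from the shifted parametric distribution rather
  than resampled from the patient table: the patients are themselves draws
  from the unshifted distribution, so the planted trial-vs-population gap
  equals the configured shift in expectation exactly, which the calibration
  and power tests rely on. Trials alternate between reporting mean/SD and
  median/IQR of their simulated enrolees; trials with fewer than two enrolees
  are excluded with a log message.

One global integer seed feeds fixed per-table substreams
(`default_rng([seed, stream_key])`), so each table is bit-identical across
runs and regenerable in isolation.

**What the generator does not emulate:** real geography (coastlines, road
networks — the coastal flag carries a planted linear effect only), spatial
autocorrelation of area covariates, temporal trends in recruitment, subtype
misclassification, and any correlation between deprivation and distance
beyond the planted coefficient. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Numerical and design choices

* Haversine is clamped (`asin(min(1, √a))`) so antipodal rounding cannot
  produce NaN; the metric-property suite (symmetry, identity, triangle
  inequality) holds to 1e−9 km on random triples.
* Degenerate Welch inputs (both SDs zero) return p = 1 when means are equal,
  ±∞ t otherwise, with a log message.
* The Cochran–Armitage trend statistic uses the score-test variance with
  equally spaced scores 1..k; it matches R's `stats::prop.trend.test` to
  machine precision on a frozen fixture.
* Problem sizes in the test and acceptance suites (e.g. 200 replicates of
  n = 5000 areas for coefficient-recovery coverage; 2000 null replicates for
  Welch calibration; 100 random 100×20 fixtures for the nearest-facility
  oracle) are chosen so each suite completes in seconds while keeping Monte
  Carlo error well inside the asserted margins.
* The conversion-accuracy study of the median/IQR approximation at n = 200,
  σ = 12 has an irreducible sampling floor: the difference between the Wan
  mean estimate and the same sample's mean has SD ≈ 0.34 years
  (asymptotic quantile theory), so roughly 15% of samples land outside
  ±0.5 years of the sample mean — an inherent property of three-quantile
  summaries, not an implementation artefact. Tests of "typical" conversion
  accuracy therefore assert the median-replicate error.

## Known limitations

Travel times are a speed-model stand-in unless a routing provider is plugged
in; the ecological model ignores spatial autocorrelation (no spatial error or
mixed models) and uses raw covariate units; activity definitions are
time-aggregated (no per-year trajectories); pooling is fixed-effect (no
heterogeneity modelling across trials).
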