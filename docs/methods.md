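# Methods

## Scope and model

`amiclaims` implements a diagnosis-code phenotyping algorithm for acute
myocardial infarction (AMI) and the descriptive analyses used to assess
its clinical plausibility across the U.S. ICD-9-CM → ICD-10-CM transition
of 2015-10-01. It operates on six linked flat tables (persons, enrollment
spans, diagnosis claims, drug orders, procedure claims, inpatient
admissions) that mirror the structure of person-linked commercial /
Medicare-supplemental claims databases.

The method is intentionally purely descriptive: counts, proportions and
distribution summaries, with no significance testing, no incidence-rate
estimation (only first events per period are kept, so prior history is
unknown), and no risk-model or comorbidity-index computation.

## Cohort rules and their encoding

* All dates are ISO calendar dates and **every interval is closed on both
  ends** — windows phrased as "one day before to 14 days following" are
  `(-1, +14)` inclusive.
* **Era gating**: a claim is era-valid iff (ICD-9-CM and date <
  2015-10-01) or (ICD-10-CM and date ≥ 2015-10-01). This drops overtly
  mis-dated codes and partitions every cohort's index events by version.
* **Continuous enrollment**: enrollment spans are merged (overlapping or
  day-adjacent spans coalesce) before any test; a year counts iff its
  first and last days are covered and every interior gap is ≤
  `enrollment_gap_days` (default 0, i.e. strictly continuous; the
  allowance exists for sensitivity analyses).
* **Multi-year periods**: a person is eligible for, say, 2014–2017 if
  continuously enrolled in ≥ 1 whole calendar year inside the period, and
  only claims dated inside such fully-enrolled years can index. This is
  one defensible reading of per-calendar-year eligibility applied to a
  combined period (eligibility could instead be tested only at the index
  date); the choice is localized in `cohort.eligible_person_years`.
* **Age** is `event_year − birth_year` (claims carry birth years, not
  birth dates); denominator age uses the person's first eligible year in
  the period, numerator age uses the index year. Persons younger than
  `min_age_years` (default 1) in a year are excluded from that year's
  numerator and denominator.
* **Tie-breaking** for same-day qualifying claims is deterministic:
  inpatient setting first, then principal > secondary > unspecified
  position, then lexicographic code order. Input row order never affects
  output.

## Code patterns and GEM mapping

Wildcard patterns use lowercase `x`, one character each; a *trailing* run
of wildcards also matches absence (`I21.xx` covers I21, I21x and I21xx
shapes). Codes are stored undotted and uppercase; dotted forms are
accepted on input only.

Forward-backward mapping applies the forward GEM to a seed set, the
backward GEM to the result, and reports `backward − seed` as newly
discovered candidates. Defaults: **one pass** (`iterations=1`), because
further additions belong to human review, not mechanical closure;
multi-pass iteration to the reachability fixed point is opt-in and is
verified against a brute-force closure oracle in the tests. No-map
entries contribute no codes but are preserved in the per-code provenance;
combination-mapping entries contribute their single target with the flag
surfaced. GEM files are inputs — the packaged GEM fixtures are synthetic
toys for tests and examples, not a CMS release.

## Characterization conventions

* **Rounding**: printed percentages are half-away-from-zero to 1 decimal;
  per-1,000 proportions to 2 decimals. (One published demographic cell,
  44.9% for 120,789/268,424, is not reproducible under any rounding of
  its printed counts — 45.0026% — so the package documents its rounding
  and does not chase that cell.)
* **Frequency tables** count each person once per item, ranked by person
  count descending then item ascending; the index claim's own code is not
  excluded, so additional in-window algorithm codes are counted.
* **Drug classes** use the top-100-products rule: products are ranked by
  in-window person count, the top 100 are mapped to classes, and a person
  counts once per class. Because the class table is a *cardiac* medication
  table, products mapped to a non-cardiac category are dropped, while
  products absent from the category map fall into `other`. Class totals
  are a floor, not an exhaustive assessment of each class.
* **IQR** uses median-exclusive quartiles (medians of the lower/upper
  halves, excluding the overall median when n is odd); Tukey hinges would
  differ slightly and no method is canonical for this kind of report.
* **LOS** is floored at 1 day (`max(1, discharge − admit)`) so same-day
  stays count as one day, consistent with reported ranges starting at 1.
  Each inpatient-cohort person links to the admission containing (or
  starting on) the index date, earliest admission first; unlinkable
  persons are excluded and counted in `n_unlinked` (and logged).
* The EKG "any of three codes" query is a configurable code set
  (`resources.EKG_CODE_SET`: 93000/93005/93010 — tracing with
  interpretation, tracing only, interpretation only), since the services,
  not the codes, define the query.
* The gender-age curve is emitted both by single year of age and by the
  standard bins (0–17, 18–34, 35–44, 45–54, 55–64, 65+), with
  zero-denominator cells suppressed.

## The synthetic generator

The generator emulates the *marginal* structure the analyses assume,
calibrated by default to the published descriptive frequencies:

| parameter | default | meaning |
|---|---|---|
| `annual_ami_rate_per_1000` | 3.0 | per-year case probability per enrollee |
| `setting_mix` (inpatient) | 0.634 | index-claim setting distribution |
| `case_age_mix` (65+) | 0.449 | age-bin mixture for cases (0.2/1.7/5.1/16.2/31.9/44.9%) |
| `male_prob_case` / background | 0.614 / 0.481 | gender mixtures |
| `both_version_prob` | 0.093 | share of 2015 cases with codes in both eras |
| `concurrent_marginals` | per-code | e.g. I10 0.516, R07.9 0.435, I25.10 0.435 |
| `ekg_any_prob` | 0.79 | probability of ≥ 1 EKG code in window |
| `los_band_probs` | 0.699/0.178/0.054/0.069 | LOS band distribution |
| `enrollment_gap_prob` | 0.02 | probability of a 30-day mid-study coverage gap |

Mechanics and their consequences:

* Ages are drawn per bin, uniform within bin (65+ truncated at 95; case
  ages start at 1 so a case is never infant-excluded); cases draw their
  age at the first case year, background persons at study start.
* Case years are Bernoulli per enrolled year; a 2015 case is, with
  probability `both_version_prob`, forced to index in January–September
  (ICD-9-CM) with a second ICD-10-CM claim in October–December — making
  the configured value the exact "both" share among 2015 cases.
* Concurrent diagnoses take their ICD version from *their own* service
  date's era, so windows that straddle 2015-10-01 never violate era
  consistency; the configured per-code marginal is therefore attenuated
  by a ~2-day boundary effect, negligible away from the transition.
* Within-band LOS is uniform on integer days; the > 14 band uses a
  geometric tail (p = 0.1) capped at 384 days. Band proportions are
  reproduced exactly in expectation; mean/SD/median are emergent, not
  calibrated.
* EKG codes are drawn conditionally on an any-EKG Bernoulli draw
  (per-code probabilities scaled by 1/`ekg_any_prob`, with the most
  common code forced when the conditional draw yields none), so the
  any-EKG rate is exactly calibrated and per-code marginals approximate.
* Background noise (non-algorithm diagnoses from a decoy list disjoint
  from the concurrent-marginal codes, non-cardiac drug orders, routine
  procedures) is sprinkled uniformly over the study period to exercise
  the window and code filters.
* One RNG stream per table, split from the master seed
  (`numpy.random.SeedSequence.spawn`), so bundles are reproducible at the
  record level and adding a table never perturbs earlier ones.

What the generator does **not** model: joint distributions beyond case
status (no age × drug-class or setting × LOS structure), claim
adjudication and costs, processing lags (a single service date per
claim), care-type distinctions, and race/ethnicity. Passing calibration
tests therefore demonstrates that the *engines* recover configured
marginals, not that the synthetic data is realistic in joint structure.

A per-person `ground_truth` table (case status, index event, LOS, attached
in-window items) is emitted from the same draws, enabling exact
sensitivity/specificity verification of the cohort engine: on clean
synthetic data, recovery is exact by construction, and decoy codes leave
cohorts unchanged.

## Problem sizes and verification

Unit and property tests run on 20–4,000-person bundles, with brute-force
per-person oracles (cohort scan, windowed counting, GEM closure) on
bundles of ≤ 200 persons. End-to-end calibration recovery uses 20,000
persons in the test suite and 200,000 persons in the acceptance script,
with agreement required within 3 binomial standard errors of each
configured marginal — at 200,000 persons (~2,400 cases) that is roughly
±3 percentage points on the 65+ share and ±3.5 on the 1–5-day LOS band.

## Known limitations

* The packaged code list encodes the four pattern families; a fully
  enumerated per-code list (with per-code descriptions) would be needed
  to reconcile against an external registry release.
* GEM direction inference is heuristic (ICD-10-CM sources start
  letter+digit); pass the direction explicitly for ambiguous files.
* The multi-year eligibility reading above affects combined-period
  denominators; per-year results are unaffected.
* Proportions are per-1,000 *enrollees with ≥ 1 fully enrolled year*,
  not incidence rates; first-event deduplication makes rates
  unidentifiable by design.
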