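# Methods

This note documents the statistical model, the conventions the package
fixes where spontaneous-report practice varies, the synthetic-data
generator, and the package's known limitations.

## Disproportionality model

All four estimators operate on the four-grid (a, b, c, d) of one
drug–event pair over N deduplicated reports. The counting unit is the
report: a report contributes at most one to each cell, and a report
listing the drug plus two matching events still adds one to `a`. The
comparison universe defaults to the entire deduplicated database (all
drugs, all events); `universe_scope="bite"` restricts it to reports
mentioning a dictionary drug for sensitivity analyses.

* ROR and PRR use lognormal Wald intervals at z = 1.96 (two-sided 95%).
* The χ² statistic is the uncorrected Pearson form
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); the Yates continuity correction is
  available by flag but off by default.
* The BCPNN point IC is the simplified log₂ observed/expected ratio,
  which makes IC = log₂(EBGM) an exact identity; the Bayesian machinery
  affects only the bound. IC025 = E(IC) − 2√V(IC) uses the standard
  Dirichlet-prior moments with α₁ = β₁ = γ₁₁ = 1, α = β = 2 and the
  derived joint prior total γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)), with
  the three-term variance divided by (ln 2)² to express it in bits.
  With a = 0 the point IC is undefined but IC025 remains computable.
* EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)): a one-sided 5%
  bound on the same lognormal scale. The "MGPS" here is the
  observed/expected relative reporting ratio with this bound; full
  DuMouchel gamma-mixture shrinkage is intentionally out of scope.
* Zero cells are never continuity-corrected (no +0.5). The affected
  method is reported as non-evaluable (NaN, flag false) instead; the
  ROR/PRR criteria already require a ≥ 3, so correction would only
  manufacture signals the criteria reject. a = 0 pairs are carried
  through the batch output (flagged non-evaluable) so row sets are
  stable across runs.

Signal criteria: ROR and PRR positive iff a ≥ `min_a` (default 3) and
the CI lower bound > 1; BCPNN positive iff IC025 > 0, graded
low (0, 1.5], medium (1.5, 3], high (> 3) bits; MGPS positive iff
EBGM05 > 2 (strict) and a > 0; combined positivity requires all four.
No multiple-testing adjustment is applied across pairs.

A note on monotonicity: ROR and PRR are strictly increasing in `a`
with b, c, d held fixed, but EBGM (hence IC) also grows both margins
and N, and on small tables can plateau or decrease; it is strictly
increasing exactly when bc > a(a+1). The property tests assert this
corrected statement.

## Data model and deduplication

FAERS stores every revision of a case as a separate report row.
Deduplication keeps exactly one row per `caseid`: the highest
`caseversion`, ties broken by latest FDA receipt date, then highest
`primaryid` — the conventional FAERS rule, fixed here so counts are
reproducible. All downstream tables are filtered to retained report
ids. The operation is idempotent and the output size equals the number
of distinct case ids.

Field conventions:

* Dates: only full YYYYMMDD values parse; partial dates (YYYYMM, YYYY)
  are treated as absent and excluded from interval arithmetic rather
  than imputed to mid-period, to avoid fabricating onset times.
* Age: unit codes YR/DEC/MON/WK/DY/HR convert to years; a bare value
  in (0, 120] is taken as years; results outside [0, 120] are dropped
  (plausibility bound 120 years).
* Country: occurrence country preferred, reporter country as fallback.
* Drug roles: all of PS/SS/C/I count by default, with a filter option
  (e.g. PS,SS) since reporting practice on role codes is inconsistent.
* Drug matching is case-insensitive substring over both the verbatim
  name and the active-ingredient field, because FAERS drug names are
  free text; a mention matching two canonical drugs is assigned to
  both. The shipped PT→SOC table is a minimal two-column file covering
  the analysis vocabulary (MedDRA cannot be redistributed); a licensed
  export drops in via the same format.

## Time to onset

TTO = event date − earliest therapy start date for the implicated drug
within the report, in whole days, with same-day onset mapped to 1
(reported minima in spontaneous data are one day). Negative intervals
and missing/partial dates are excluded and tallied in the run log.
When a case has several therapy episodes for one drug the earliest
start is used (first exposure). The headline presentation is mean with
range, with median and quartiles always computed alongside because
spontaneous-report TTO is heavy-tailed (mean ≫ median).

## Descriptives

Cohort tables are computed over the NST case set (deduplicated reports
with a matched drug and ≥ 1 NST event), one row per (case, drug)
assignment, so a case listing two BiTEs appears under both drugs and
the total column is the sum of the drug columns. Means and SDs use
present values only; missing age/weight is never imputed; unknown sex
is its own category. A case with several outcome codes is tabulated
once under the most serious (death > life-threatening > disability >
required-intervention > hospitalization > other-serious > unknown).
Percentages are count/n × 100 with decimal half-up rounding to two
decimals (float rounding is banker's and differs on exact .005
boundaries). Country counts use a configurable named list with an
"Other countries" bin.

## Synthetic-data generator

The generator emulates the structure the pipeline needs to be tested
against: multi-version duplicate case reports, free-text drug names
(brand/ingredient variants), PT-coded events, demographic mixtures,
and therapy/event dates with heavy-tailed onset.

Generative model: per-report drug and event mentions are independent
Bernoulli draws on configurable marginals, except planted
dependencies: for a planted (drug, event, rr) the event's conditional
probability given the drug is rr × its background probability, capped
at 0.95 (a hit cap is logged and flagged in the manifest). Because the
planted ratio is defined against the *background* rate, the drug's own
excess reports inflate the database-wide event margin by roughly
1 + (rr−1)·p(drug); disproportionality estimates therefore recover rr
only up to that attenuation, which is why the default drug marginals
are small (≤ 0.02, giving ≤ 10% attenuation at rr = 50).

Defaults (the study conditions for all tests): 10⁵ cases; nine BiTE
drugs with marginals 0.001–0.02 (scaled up relative to the real
database, where BiTE reports are ~4 × 10⁻⁴ of the total, so that
desk-scale runs yield evaluable cell counts); 18 events — ten
neurological PTs plus common background events — with marginals
0.002–0.08; planted signals blinatumomab–neurotoxicity rr = 3,
tarlatamab–ICANS rr = 50, and a rr = 1 null control; duplicate
fraction 0.10. Age is normal per drug with the published per-drug
means/SDs; sex, country and outcome frequencies follow the published
cohort mixture; onset is log-normal per drug (σ = 1.0 on the log
scale) with means matching the published per-drug onset means
(blinatumomab 27.1 d, tarlatamab 16.7 d, glofitamab 82 d, teclistamab
81.6 d, others 30 d). Duplicates perturb only mutable fields (weight,
reporter occupation) and copy their child rows under the new report
id, so dedup correctness is observable end to end.

What the generator does *not* emulate — so passing tests show pipeline
correctness, not real-world fidelity: co-reporting correlation between
drugs and between events, reporting-bias phenomena (Weber effect,
masking, stimulated reporting), realistic marginal calibration,
LLT-level coding noise, and probabilistic duplicates across different
case ids.

Test problem sizes: the recovery checks run one 10⁵-case dataset for
the planted ratios and ten 10⁵-case null datasets for the
false-positive rate; interval calibration uses 2,000 multinomial
resamples of a fixed four-grid at N = 10⁵. These sizes put Monte Carlo
error well inside the stated tolerances (expected a of 60–160 for
planted pairs gives ≲ 13% sampling SD on EBGM against a ±25% band)
while keeping the full suite under a minute.

## Known limitations

* The MGPS implementation is the unshrunk relative reporting ratio
  with a lognormal bound, not DuMouchel's gamma-Poisson mixture; for
  very small a it is anti-conservative relative to true EBGM
  shrinkage (mitigated by the a ≥ 3 and EBGM05 > 2 criteria).
* Duplicate detection is by case-version only; probabilistic record
  linkage across different case ids is out of scope.
* The shipped vocabulary covers the NST analysis; it is not a MedDRA
  substitute, and SMQ-based event selection is not implemented.
* Stratified (age/sex/year) contingency tables are not implemented;
  the universe-scope option is the only confounding control offered.
* Published signal tables from the full database are not exactly
  reproducible from a desk: they require the complete FAERS archive
  and a licensed MedDRA release. The package's acceptance checks
  therefore target in-table arithmetic identities and
  simulation-recovery properties instead.
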