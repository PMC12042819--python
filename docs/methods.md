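# Methods

This note documents the survey model implemented by `vcsurvey`, the choices
made where the field protocol leaves room, and what the simulation results
do and do not establish.

## The design

The survey is a stratified three-stage cluster design.  Every health zone
(HZ — the district-equivalent operational unit) is a stratum, so estimates
are representative at the HZ level and can be pooled upward to province and
national levels without losing any HZ.

1. **Stage 1 — health areas (PSU).**  The HAs of a HZ are sorted
   alphabetically (plain codepoint order, so the numbering is reproducible
   across systems) and numbered; 5 primary HAs plus 2 replacements are drawn
   with a random number generator, redrawing duplicates.  Redraw-on-duplicate
   is probabilistically equivalent to simple random sampling without
   replacement, which is how it is implemented; π₁ = 5/N_HA.  Replacement
   HAs substitute primaries only where access is insecure.  If a HZ has ≤ 5
   HAs, all are taken (π₁ = 1) and the per-HA household quota is inflated to
   ⌈5·30 / N_HA⌉ so the HZ total of 150 households is preserved — the rule
   keeps every HZ sample above the largest per-province minimum sample size
   (144.0).
2. **Stage 2 — segments (SSU).**  Two variants.  *Legacy (2020–21)*: named
   street/village segments are listed and 30 % selected by SRS; the count is
   ⌈0.30·N⌉ with a minimum of one so the selection is never empty.
   *Quadrant (2022–23)*: the HA is partitioned into a 4×4 grid of 16 cells
   and 6 are drawn a priori (π₂ = 6/16), dispersing households and removing
   the "pocketing" bias of the legacy listing.
3. **Stage 3 — households (TSU).**  In each selected cell the field team
   identifies eligible households (a child aged 6–23 months) up to a
   stopping count (18 in 2022, 15 in 2023) and samples 5 systematically:
   interval I = N/k, start u ~ Uniform(0, I], 1-based indices ⌈u + jI⌉.
   The fractional-interval rule gives every roster entry inclusion
   probability exactly k/N for any N, integer interval or not.  A household
   absent after three visits is replaced by the next not-yet-selected roster
   entry (wrapping); an exhausted roster leaves the slot unfilled and flags
   a shortfall.  In the legacy variant the systematic draw of 30 households
   is made once per HA from the roster pooled over its selected segments.

Every enrolled household carries π₁π₂π₃ and the base weight 1/(π₁π₂π₃).
No post-stratification or non-response adjustment is applied beyond the
replacement rule — the protocol defines none.  All randomness flows from a
single seeded generator, so a plan is bit-reproducible from its seed.

Sample size per province uses n = deff·Z²·p·q/d² on the percent scale with
deff = 1.5, Z = 1.96, d = 10 and p the anticipated provincial coverage.
Reported values round half-up to 1 decimal (`decimal.Decimal`, not float
banker's rounding); the operational target is the ceiling.

## Indicators

Doses are consolidated per (antigen, dose number) with source precedence
card > facility record > caregiver recall; a dose counts if any source
attests it (the crude, possession-based convention — recall-only doses
count).  Zero-dose means no pentavalent dose from any source.  Fully
vaccinated means possession of BCG, Penta×3, PCV×3, Rota×3, OPV×3, measles
and yellow fever (the schedule is a configurable mapping).  Card possession
records only that a home-based record was seen, independent of its
completeness.  Dose dates are out of scope, so age-valid ("by the first
birthday") tabulations are not computed; cohorts 6–11 and 12–23 months are
reported separately instead.

## Estimation

The point estimate is the Hajek ratio Σwy/Σw.  Variance is the stratified
ultimate-cluster linearisation: cluster residual totals z_hi = Σ w(y − p̂),
v̂(p̂) = Σ_h n_h/(n_h−1) Σ_i (z_hi − z̄_h)² / (Σw)².  This is the
with-replacement first-stage approximation standard in survey software; no
finite-population correction is applied.  Strata with one sampled cluster
are certainty units (zero contribution, warning logged).  Aggregation to
province/national level re-estimates over the pooled child records with HZ
strata intact — it is not an average of HZ point estimates.

DEFF = v̂(p̂)/[p̂(1−p̂)/(n−1)]; ICC = (DEFF−1)/(m̄−1) from the equal-cluster
identity.  DEFF is reported as missing when p̂ ∈ {0, 1}.

**Confidence intervals.**  Wilson score intervals computed on an effective
sample size.  Two conventions coexist deliberately:

* the bare `confidence_interval(point, effective_n)` uses the normal
  quantile — the textbook Wilson form;
* the estimation pipeline uses a Student-t quantile with
  df = #clusters − #strata (4 for a single HZ), the small-PSU convention of
  coverage-survey practice, and computes the interval on the *unclipped*
  variance ratio n/DEFF.  The reported `n_eff` column keeps the
  conventional clipping n/max(DEFF, 1) ≤ n, but clipping inside the
  interval would discard genuine efficiency gains of systematic/stratified
  selection (DEFF < 1) and, combined with the t quantile, systematically
  over-cover at low ICC.  With the unclipped ratio the interval tracks the
  estimated design variance and the t quantile compensates for its 4
  degrees of freedom; measured coverage is ≈ 94–96 % at ICC 0–0.2.

## The synthetic population

The generator emulates structure, not any real country's coverage values:

* 26 provinces, 519 HZs (11–36 per province); HA counts per HZ from a
  banded discrete distribution with support [4, 41] and mean ≈ 18; HA
  populations uniform on 5 000–10 000 persons.
* Eligible children (6–23 months) are a binomial fraction of the HA
  population, default 0.05 — consistent with an 18-month birth cohort at a
  high crude birth rate.  About 5 % of eligible households hold two
  eligible children; all eligible children of a sampled household are
  enrolled.
* Coverage hierarchy: HZ mean μ ~ Normal(0.6, 0.1) clipped to [0.02,
  0.98]; HA coverage ~ Beta with mean μ and concentration α+β = (1−ρ)/ρ,
  so the induced child-level ICC is exactly ρ (Beta ICC = 1/(1+α+β));
  cell-level coverage tilts on the logit scale by a centred near-centre
  gradient scaled by the pocketing coefficient; children are Bernoulli
  given their cell.  30 % of unvaccinated children are partially vaccinated
  (BCG + Penta1) so zero-dose, Penta and fully-vaccinated indicators are
  distinct.
* Evidence: each child holds a card with probability 0.6 (≈ the observed
  national HBR availability); cardless children are facility-traced with
  probability 0.3, otherwise recall.  Households are absent with
  probability 0.05 and replaced by the next-in-roster rule.
* The *near-centre* legacy mode lists only the half of the segments closest
  to the grid centre before the 30 % selection — a simulator behaviour
  reproducing the documented field bias, not a recommended design.

What the generator does **not** emulate: real geography (cells are an
abstract grid), seasonal and access-related non-response structure,
age-dependent schedules and dose timing, reporting errors in recall, or any
real coverage surface.  Passing calibration therefore shows the estimator
and intervals are faithful to the declared design under controlled
clustering — not that any specific real-world estimate is correct.

## Calibration results and problem sizes

`calibrate` runs the full loop on one typical HZ (18 HAs, ~150 enrolled
households, ~154 children) per replicate, 500 replicates per ICC scenario
{0, 0.05, 0.2} — small enough to run in about a minute, large enough that
Monte-Carlo standard errors are ≈ 0.1–0.6 pp for bias and ≈ 1 pp for CI
coverage.  The estimand is the replicate's latent HZ mean μ: with small
first-stage sampling fractions the finite-population proportion and μ
coincide in expectation, and μ is the target consistent with the
with-replacement variance convention.  The pocket experiment uses the
realised population proportion instead, since pocketing makes the latent
and realised quantities differ systematically within a replicate.  The
equal-cluster DEFF check (30 clusters × 30 children) verifies
E[DEFF] ≈ 1 + (m̄−1)·ICC within Monte-Carlo error.

## Known limitations

* The ultimate-cluster variance omits finite-population corrections; with
  5 of ~18 HAs sampled per HZ it is mildly conservative for the
  finite-population estimand.
* With 5 PSUs per stratum any interval method is approximate; the t-Wilson
  convention measured ≈ 94–95 % coverage, slightly under nominal, which is
  typical for this family at 4 df.
* Weights assume the eligible-household stopping rule censors the roster at
  random (the simulator randomises roster order); a systematic field
  ordering would bias π₃.
* Segment rosters for the legacy protocol must be supplied (or simulated);
  the package does not attempt to reconstruct street lists.
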