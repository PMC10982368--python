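# Methods

## Setting and counting model

`faersig` screens a spontaneous-reporting database for drug–event pairs
reported more often than expected under independence. The unit of analysis
is the **deduplicated case**: FAERS reissues a case (CASEID) as multiple
report versions (PRIMARYID), and the FDA-recommended rule retains, per
case, the version with the maximum FDA receipt date, ties broken by the
maximum PRIMARYID. Both comparisons are numeric, never lexicographic,
because identifiers may differ in digit count. Records with a missing
CASEID are conservatively kept as singleton cases and counted in the run
warnings rather than dropped.

Event counting is **report-level with set semantics**: a report
contributes at most one count per distinct preferred term (PT), however
many duplicate reaction rows it carries. PT text is canonicalized before
any counting (whitespace collapsed, sentence case) because FAERS casing is
inconsistent across quarters and a split count would bias every statistic
downward.

The target cohort comprises deduplicated reports in which a drug matching
the configured name patterns (generic plus brand spellings; word-bounded,
case-insensitive substring matching so that dose/form suffixes match but
lookalike molecule names do not) carries role *primary suspect*, and the
reporter is a healthcare professional (MD, PH, OT). The comparator is
every other report under the *same* reporter filter, so numerator and
denominator cohorts are curated identically; an unfiltered comparator is
available behind a flag. "Primary suspect" is read as *the target drug
appears with role PS*; a strict mode additionally requires that no other
drug in the report is a primary suspect. Four SOCs conventionally
considered unrelated to drug action (injury/poisoning/procedural
complications, product issues, surgical and medical procedures, social
circumstances) are removed from the event stream before screening; removal
counts are logged.

## Disproportionality statistics

For each event term with at least one target report, the 2×2 table
(a, b, c, d) yields:

**ROR** = ad/(bc), CI = exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)). The
normal quantile is used at full precision (1.95996…) so the interval
matches generic log-odds-ratio machinery to numerical precision; at two
printed decimals this is indistinguishable from the conventional 1.96.
If any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe)
and the result is flagged `corrected`. Tables with an empty margin are
tagged undefined, never silent NaN.

**BCPNN information component.** Raw IC = log₂(aN/((a+b)(a+c))). The
Bayesian version shrinks toward 0 using the standard prior pseudo-counts
γ₁₁ = α₁ = β₁ = 1, α = β = 2 (the source analysis cites the method without
its constants; these are the published defaults):

- γ = γ₁₁(N+α)(N+β) / ((a+b+α₁)(a+c+β₁))
- E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
- V(IC) = (ln 2)⁻² · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
  + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
  + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]
- IC025 = E(IC) − 2√V(IC)

A Monte-Carlo alternative draws the joint and the two marginal reporting
probabilities from their independent Beta posteriors under the same priors
and takes the 2.5th percentile of the sampled log₂ ratio; it serves as the
validation oracle for the closed form.

**Accuracy of the closed form.** Measured against the 200k-draw posterior
percentile, E(IC) − 2√V(IC) agrees to ≤ 0.2 bits once a ≥ 10 (typically
≤ 0.03), but at a = 3–9 under strong shrinkage it can sit up to ~0.4 bits
*above* the exact percentile — the normal approximation is
anti-conservative exactly where the N ≥ 3 gate admits the smallest
signals. The test suite pins this behavior (0.2 bits for a ≥ 10, 0.5 bits
for 3 ≤ a < 10, upward direction); for borderline small-N signals the
Monte-Carlo percentile is the better arbiter.

A related caveat: in the source analysis's printed tables the gap between
IC and IC025 is nearly constant (≈1.66 bits) across report counts from 3
to 817, which no standard BCPNN variance reproduces — the posterior
variance must shrink with a. This package implements the standard
formulations and reports both the raw and the shrunk IC rather than
reverse-engineering an undocumented convention; printed "IC" columns in
such analyses often track log₂(ROR) closely, so both views are emitted.

**Decision rule.** A term is of interest iff ROR CI lower bound > 1 with
a ≥ 3 *and* IC025 > 0. No multiplicity adjustment is applied (matching
field practice for hypothesis-generating screens); an FDR column can be
enabled in principle but is deliberately off. Ranked output breaks ties by
descending report count, then term name, for byte-reproducible tables.
PT-level results carry an annotation against the 23-term list of
labelled/expected reactions for the default target drug.

## Descriptives, time to onset, subgroups

Ages are normalized to years (decade/month/week/day/hour unit codes; a
bare value between 18 and 120 is accepted as years), floored to completed
years, then banded ≤17 / 18–64 / 65–85 / ≥86 / Unknown. Weights convert to
kg (<50 / 50–100 / >100 / Unknown; band edges read as printed, i.e. 50 and
100 belong to the middle band). Daily dose is defined only for mg doses
with a recognized frequency code (QD/BID/TID/QID/QOD). Medication duration
is the calendar-day difference end − start (same-day therapy = 0 days),
requiring day precision at both ends; the duration bins label the last
band ">361" as conventionally printed while internally binning every day
> 360 so no value is unbinnable. Percentages are rounded half-up to two
decimals. Outcome panels count each case at most once per outcome code and
are intentionally non-exhaustive (a case may carry several codes or none).

**Time to onset** is the day count from the earliest day-precision therapy
start linked to the matched primary-suspect drug to the report's
day-precision event onset date. Partial dates and negative intervals are
excluded and counted. Quantiles use linear interpolation (the common
default in scientific software; the convention is not fixed by the field).
Bins are 0–30 (inclusive both ends), 31–60, 61–90, 91–180, 181–360, >360.

**Subgroups** re-run the identical screening machinery inside a stratum
(weight band, continent via a country→continent table, or co-reporting of
a named concomitant drug in any non-target role). Both cohorts are
restricted to the stratum by default — a within-stratum 2×2 — with a
global-comparator switch. "Top terms by signal intensity" means descending
ROR among of-interest terms. Country→continent resolution falls back to a
bundled table covering the generator's countries; real analyses should
supply their own file.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with every quantity bookkept as ground truth:

- **Cohorts**: 2,000 target and 20,000 comparator reports by default —
  a deliberately scaled-down database in which the curated target cohort
  (~1,000 reports after the reporter and role filters) is comparable to a
  real single-drug HCP cohort, while the comparator stays small enough for
  sub-minute replicates.
- **Events**: ~100 PTs from the toy ontology with background rates of
  0.4–8% (common constitutional terms highest). Target reports draw a
  planted PT with probability min(1, RR·p); the default plants relative
  risk 5 on a 1% background-rate PT. Reports that draw nothing receive one
  filler term from the *non-planted* vocabulary so planted counts remain
  exactly binomial in both cohorts. Note the screen estimates an odds
  ratio: the implied OR is RR(1−p)/(1−RR·p) — 5.2 for the default — so
  recovery checks compare against the planted RR with that distortion in
  mind (it is <5% here by design of the default rates).
- **Duplicates**: 10% of cases emit 2 (occasionally 3) versions with
  non-decreasing receipt dates and version-suffixed PRIMARYIDs; 5% of
  duplicate chains share the final FDA date so the PRIMARYID tie-break is
  exercised. Dedup must recover the true case count exactly.
- **Dates**: receipt dates fall in a configurable number of calendar
  quarters spanning 2012–2023; onset times are lognormal(μ = ln 25,
  σ = 1.76), chosen to give a 25-day median with an IQR ratio matching a
  strongly right-skewed onset profile; 1% of reports get a negative
  interval to exercise the exclusion path.
- **Missingness** mirrors spontaneous-report reality: weight known 11%,
  age 57%, dose 16%, onset date 35%, day-precision therapy start 60% —
  leaving roughly a fifth of reports TTO-evaluable.
- **Demographics**: 60/35/5 female/male/unknown; reporter occupations with
  55% healthcare professionals; country mix dominated by US/JP/GB; 1–5
  co-prescribed drugs per report from a fixed pool so concomitant
  subgrouping and co-drug ranking have known answers.

What the generator does *not* emulate: the ~25k-term real PT vocabulary
and its frequency spectrum, drug-name misspellings beyond fixed brand
variants, demographic correlations (e.g. age–indication), inter-drug
correlation structure, and secular reporting trends. Passing tests
therefore demonstrate correctness of the pipeline's logic and calibration
under the generator's assumptions — not performance on raw FAERS, where
curation details (name cleaning, unmapped terms, archive corrections)
dominate small-count signals.

## Verification strategy

- Formula oracles: hand-computed ROR/CI values; agreement with generic
  log-odds-ratio interval machinery (statsmodels) to 1e−9 on 1,000 random
  tables; exact independence ⇒ raw IC 0 (property-tested); Monte-Carlo
  posterior percentile versus the closed form as above.
- Planted-signal study at the default conditions: 100 seeds ⇒ the planted
  PT is flagged in ≥95% of replicates and its ROR CI covers the planted
  effect at roughly nominal frequency (≥88% allows three binomial standard
  errors at n = 100); 40 null seeds (nothing planted) keep the mean
  flagged fraction of screened PTs below 2%.
- Structural invariants: dedup idempotence and order invariance
  (hypothesis), attrition conservation in the run manifest, byte-identical
  regeneration per seed, file round-trips.

## Known limitations

- Disproportionality is hypothesis-generating; nothing here estimates
  incidence or causality, and no multiplicity control is applied.
- Only the primary SOC of each PT is modelled (no MedDRA multi-axiality,
  no HLT/HLGT/LLT, no SMQs); unmapped PTs are screened at PT level only.
- Legacy (pre-2012Q4) column layouts are supported only through the alias
  table actually needed for the 2012 quarters; ISR-era files are out of
  scope, as is the FAERS XML dialect and any automatic downloading.
- The closed-form IC025 is anti-conservative at a < 10 (see above).
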