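# Methods

This note documents the analysis model, its tunable parameters, the
numerical choices made where the procedure was genuinely open, what the
synthetic data emulate, and the known limitations.

## Claim model and dose estimation

A claim is one dispensing event: date, drug, unit strength (mg), quantity,
optional days-supply, zero or more ICD-10 codes. Drug classes come from a
packaged formulary CSV (override with your own via config); unknown drugs
sink to `OTHER`. The days-supply column is deliberately ignored everywhere —
it is present only for part of the window in databases of this kind and is
unreliable — so supply duration is always `quantity / estimated daily dose`.

The daily dose defaults to **one unit per day** unless the refill pattern
itself gives evidence of an alternative: at least two inter-claim gaps, a
stable gap length (≥ half the gaps within ±25% of the median), and a
median-quantity/median-gap ratio within ±20% of a plausible value
{0.5, 1, 1.5, 2, 3} units/day. The ±20% acceptance window is deliberately
conservative: a single delayed refill (one long gap) or a ratio such as 0.69
must not masquerade as evidence for a half-unit dose, or the worked
segmentation examples fall apart. One isolated gap is never evidence.

## Monthly plotting and TAG

The issuance grid spans the 60 study months. When exactly two same-type
dispensing dates fall in one calendar month, two reassignment rules may move
one of them a single month (never further, and a claim moves at most once;
unit totals are conserved):

* **Rule 1** — gap ≥ `rule1_min_gap_days` (21) and an adjacent month empty,
  with both claims matching the modal (drug, strength, quantity) signature
  of a ±3-month window; the claim nearer the empty month moves into it.
* **Rule 2** — the window's units-per-day ratio matches the estimated dose
  within `rule2_tolerance` (±20%); the later claim is attributed to the
  following (empty) month.

Claims whose implied coverage is below `short_supply_days` (14) are flagged
and never counted as a month of medicine coverage. TAG requires ≥
`tag_total_min` (12) qualifying months over the window **and** ≥
`tag_window_min` (7) within any `tag_window_months` (12) rolling span; both
criteria are listed as one clause in the source methodology, so the
conjunction is the default and an OR policy is available
(`--tag-policy or`). A month supplied with both drug types counts once.

## PDC period segmentation

Assessment periods are anchored on issue dates and segmented greedily left
to right; the nominal period is 90 days. With `s` the period start, window =
issues before `s + 90`, and `next` the first later issue:

1. **Database end** — a terminal period is truncated at the day after the
   last study day (coverage clipped), since later refills are unobservable.
2. **Less than 90** — if some calendar month inside the window has no issue,
   the last in-window issue lies within `lt90_proximity_days` (14) of the
   nominal end ("slightly before"), and a tentative period opening there
   would hold ≥ 60 covered days, the period closes early at that issue. The
   14-day proximity is what separates the early-close scenario from the
   regular-but-late scenario below, both of which contain an empty month.
3. **120–129** — `next` falls 120–129 days after `s` under a regular pattern
   (identical drug/strength/quantity): the period closes at `next`.
4. **Up to 119 / over 90** — a period with a successor closes at `next`
   (91–119 days); without a successor it extends to the calculated supply
   end, capped at 119 days.
5. **Standard 90** otherwise.

Rule precedence: database-end > less-than-90 > 120–129 > up-to-119 >
over-90 > standard.

Refill gaps placing `next` more than 129 days after `s` close the running
episode terminal-style and open a fresh period at `next`. The period
sequence is therefore contiguous within a treatment episode but not across
drug holidays or discontinuation — an intentional break is not scored as
non-adherence, and no period exceeds 129 days. Covered days are the exact
union of half-open supply intervals clipped to the period (overlaps never
double-count; day counting is the start-exclusive difference `end − start`).
Per-patient, per-drug-type adherence is the **unweighted** mean of period
PDCs (duration-weighting is a defensible alternative; unweighted matches the
per-period averaging the method describes). A patient with no periods is
reported missing, never zero. Antidepressant agents are pooled into one
stream per patient with doses estimated per agent.

PDD = total mg dispensed / total covered days, per patient, over
methylphenidate claims; `mph_ddd_mg` (default 30) sets the DDD comparator.

## Cohort and filters

Cascade order is fixed: age gate (≥ 18.0 years on the first study day and
≤ 40 entering the index year), index-claim gate (a MIMS-1.1.3 claim in the
index year), flumazenil-only gate (all index-class claims are flumazenil and
no `F90*` code anywhere). F90 matching is case-insensitive on the code
prefix, any claim, any year — a diagnosis recorded late still labels the
patient's whole history. The tricyclic-misuse filter excludes TCA claims
from antidepressant analyses when the implied daily dose is below the
agent's accepted minimum antidepressant dose (formulary column), coverage is
shorter than `tca_short_term_days` (14), or the claim's codes name no mood
disorder (prefix set `F32,F33,F34,F38,F39,F41`, configurable); exclusions
are exported for audit.

## Statistics

Fisher's exact test uses the two-sided probability-mass convention, computed
by scipy and verified in the test suite against exhaustive integer-exact
hypergeometric enumeration on every 2×2 table with N ≤ 40; a zero margin
returns p = 1. Continuous PDC is dichotomised at `pdc_threshold` (0.80,
inclusive — the conventional acceptable-adherence cut-off). The TAG logistic
model (statsmodels maximum likelihood) reports per-term odds ratios, Wald
chi-square p-values, and Type-3 likelihood-ratio p-values from refits
dropping each term; age bands (20–24 reference, 25–29, 30–34, 35–39, from
age at mid-index-year) enter as dummies dropped jointly. Separation and
non-convergence are flagged in the result status rather than raised; no
multiple-testing correction is applied.

## Synthetic data

The generator emulates: monthly 30-unit methylphenidate scripts (30 mg
units, one per day → intended PDD 30 mg/day) with ±3-day refill jitter;
five archetypes — REGULAR (near-continuous refiller), HOLIDAY (two
one-month interruptions per year), DISCONTINUER (8–10 months then stop),
IRREGULAR (4–8 scattered claims), AD_DOMINANT (monthly antidepressant with
quarterly 90-unit methylphenidate) — mixed so the TAG fraction is near the
observed 32/89; antidepressants co-dispensed at the same visits; F90 codes
stamped only for F90-group patients and only outside 2012–2013 (emulating
missing early coding); a days-supply field present only on 2016 claims; and
decoys (8 under-age, 23 flumazenil-only, 5 sub-therapeutic short-course
tricyclics coded to a non-mood diagnosis) that the gates and filters must
remove. Group mix is 50:39 F90:non-F90 and gender is 50/50. At zero jitter
REGULAR streams refill on exact 30-day cycles, giving PDC 1.0 by
construction. Per-patient substreams are keyed on (seed, patient index), so
output is bit-reproducible and extending a cohort never perturbs existing
patients.

What the generator does **not** emulate: dose titration and strength
switches, therapy switching between stimulants, claim reversals, pricing or
scheme fields, and the exact demographic moments of any real population.
Passing label-recovery tests therefore shows the pipeline implements its
rules faithfully on data obeying the stated assumptions, not that those
rules are robust to every messiness of real claims.

## Problem sizes in the test suite

Oracle sweeps use 1,000 random streams for day-union coverage, all ~132k
2×2 tables with N ≤ 40 for the exact test, n = 2,000 for odds-ratio
recovery (true OR 20 recovered within [15, 26]), and a 500-patient cohort
for label recovery (exact at zero jitter, ≥ 95% at default jitter). These
sizes make every estimate's Monte-Carlo error small relative to its
acceptance band while keeping the suite quick to run.

## Known limitations

* Atomoxetine claims count toward cohort gates but are not plotted or
  PDC-assessed (negligible use in the source population).
* The segmentation rules are faithful to the documented worked examples but
  those examples under-determine some corners (e.g. competing early-close
  and late-next-issue readings); the precedence order and the 14-day
  proximity window are this package's resolutions and are recorded per
  period in the `rule_applied` / rationale fields for auditability.
* PDC within a period cannot exceed 1 because covered days are clipped;
  early refills instead surface as extended coverage in later periods.
* One claim line is assumed to be one dispensing event (no multi-pack
  splitting).
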