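# Methods

`nrt-pathways` re-implements, as a tested pipeline, a drug-utilisation
analysis of GP-prescribed nicotine replacement therapy (NRT): an
incident-user cohort anchored on a first-ever nicotine-patch
prescription, gap-based treatment-episode construction, regimen and
pathway classification, and descriptive summary tables. Because the
class of databases this analysis targets (THIN/CPRD-style UK primary
care records) is proprietary, the package ships a synthetic data
generator with the same record structure, so every stage is exercised
end-to-end without real data.

## Cohort model

A patient enters the *NRT cohort* with any NRT prescription inside the
study window (default 1 Jan 2008 – 31 Dec 2011, both ends inclusive).
Patients with NRT but no patch in the window form the *non-patch-only*
arm: they are described (seven-way product breakdown) and set aside,
since the analysis follows patch-anchored quit attempts.

For patch-cohort patients, the *index date* is the earliest in-window
patch prescription. Six criteria are then applied, all evaluated (no
short-circuiting) so attrition rows may overlap:

1. age at index < 18 years (age = index year − year of birth; the
   schema carries no birth month);
2. baseline < 183 days, where baseline runs from the latest of the
   registration, practice Vision and AMR dates to index ("6 months" is
   fixed at 183 days — deterministic and leap-year safe);
3. follow-up < 14 days, where follow-up runs from index to the earlier
   of transfer-out and the practice's last collection date;
4. any patch strictly before index (incident-user washout over the full
   record depth);
5. any non-patch NRT more than 14 days before index — an issue on day
   −14 itself is allowed, preserving combination regimens started
   shortly before the patch;
6. any bupropion or varenicline strictly before index.

A `sequential=True` flag reproduces the alternative short-circuited
accounting for sensitivity analysis; the overlapping reading is the
default because per-criterion percentages in selection flowcharts of
this design typically sum past 100.

## Episode model

NRT prescriptions (all seven forms; never bupropion/varenicline) are
scanned chronologically: a gap of ≤ 90 days between consecutive issue
dates continues an episode, > 90 days starts a new one. Consequences:

- the minimum achievable inter-episode gap is exactly 91 days;
- episode 1 starts at the index date; non-patch issues in the 14 days
  before index are merged into episode 1's product set without moving
  its anchor;
- an episode ends on its last issue date. Prescription *coverage* is
  not modelled — the schema has no quantity/duration field — so no
  coverage tail is added. This is the main interpretive caveat of the
  episode rule and is deliberately explicit.
- *discontinuation*: a patient has stopped prescribed NRT when more
  than 90 days separate the last episode's end from the end of
  follow-up; a last episode ending within those 90 days (or on/after
  follow-up end) counts as still on treatment.

Events dated after follow-up end are dropped with a warning before
episode construction. The 90-day threshold and 14-day pre-index window
are keyword parameters (defaults as above) to support sensitivity
analyses without code changes.

## Regimen and pathway classification

Categories depend on the episode's set of NRT *types* (drug classes —
strengths never count as types, so a 21 mg + 14 mg + 7 mg patch
step-down remains patch monotherapy): patch alone → `patch_only`;
patch + one partner → the matching `patch_X`; three or more types →
`three_plus_types` regardless of patch presence; patch-free episodes
(possible only for ordinals ≥ 2) → `other_monotherapy` / `other_dual`.
Letting the three-type rule absorb patch-free 3-class episodes is a
documented convention; published tables in this area list "≥ 3 types"
as a single row beside the "other" rows and do not disambiguate.

The pathway view splits each episode's products into *first-line*
(issued on the episode's start date; for episode 1, also the pre-index
window) and *add-on* (first issued later), and renders a canonical
signature over the first three episodes — products sorted by a fixed
class order (patch, gum, tablet, inhalator, lozenge, oral spray, nasal
spray) then strength label, episodes joined with `|`, missing episodes
rendered `None`. Equal clinical pathways map to equal keys whatever the
input row order.

## Reporting conventions

Table percentages are printed to 2 decimals and headline scalars to 1,
both rounded half-up (matching how such tables are normally typeset;
Python's built-in banker's rounding is not used). Episodes are
attributed to the calendar year of their start date, so second/third
episode tables can extend past the index window (e.g. into 2012).
Descriptive statistics use min/max, mean, SD with the n−1 denominator,
and median/quartiles by linear interpolation between order statistics
(even n: mean of the two central values; `{1,2,3,4}` → Q1 1.75,
Q3 3.25). Headline percentages are pure arithmetic on counts that the
pipeline also emits, so each can be recomputed from the CSV outputs.
When reporting a Table-3-style baseline summary, group Ns are always
computed from the data (a published table of this layout contains a
header/count inconsistency in one column, which the package does not
reproduce).

## Synthetic data generator

One `numpy` PRNG stream, fixed generation order (practices → patients →
prescriptions); identical seed + config gives byte-identical CSV output.
Per patient the generator draws an arm (non-patch-only with
probability 0.243), then for patch-cohort patients: an index year
(weights 10632:10501:9337:8484), an index date uniform in that year,
independent exclusion flags (under-18 0.033, short baseline 0.1579,
short follow-up 0.002, prior NRT 0.4028, prior bupropion/varenicline
0.1422), demographics, and one to three episodes.

Key default conditions and the reasoning where a choice was open:

- **Combination rates.** First episodes are combination therapy with
  year-specific probabilities (0.257, 0.339, 0.408, 0.448); the partner
  mix (gum 0.154, tablet 0.030, inhalator 0.562, lozenge 0.115,
  oral spray 0.019, nasal spray 0.009, ≥3-types 0.111) reflects the
  prescribing landscape the pipeline is meant to summarise. Second and
  third episodes draw from ten-category regimen mixes in which patch
  monotherapy falls to ~50% and ~46% and patch-free "other" regimens
  appear.
- **Repeat episodes.** A second episode starts with probability 0.202
  and a third, given a second, with probability 1926/7868 ≈ 0.245.
  Inter-episode gaps are log-normal with median 365 days and σ = 0.6,
  truncated by rejection to [91, 1693] days — the target summary
  (about a year between episodes on average, range 91–1693 days) pins
  the median and range but no distributional form; a log-normal is the
  standard pragmatic choice for waiting times.
- **Within-episode structure.** Prescriptions per episode are
  shifted-geometric (p = 0.4, capped at 8 — the cap bounds episode
  length so that late repeat episodes stay inside the collection
  window); refill gaps are uniform on [14, 35] days (fortnightly-to-
  monthly refills, comfortably under the 90-day rule). Combination
  partners' first issue falls uniformly in [index − 14 d, index + 28 d]
  for first episodes, exercising the pre-index allowance.
- **Ages.** Ages are drawn from a normal truncated to [18, 96] and
  floored to whole years. Truncating at 18 raises the mean by about
  1.9 years and flooring lowers it by 0.5, so the underlying location
  is calibrated (closed-form truncated-normal mean, iterative solve) so
  that the *realized* mean equals the configured 42.95 — the configured
  value is a property of the output, not a nominal label.
- **Oral sprays.** Not licensed until November 2010: no generated
  oral-spray issue predates 2010-11-01. Draws that would select an oral
  spray earlier are renormalized over the remaining forms.
- **Observation window.** All practices collect data until 2017-06-30
  and transfer-outs are only planted for the short-follow-up exclusion.
  This keeps every seeded repeat episode observable (a 2011 index plus
  the maximal 1693-day gap still lands inside collection), which is
  what the second-episode-rate recovery requires. The cost is that the
  generator does not emulate a realistic follow-up distribution
  (real cohorts lose patients to transfers continuously) and its
  discontinuation proportion is consequently near 100% rather than
  ~95%.
- **Planted exclusions.** Prior-patch history is dated strictly before
  the study window (so the index remains the first in-window patch);
  prior non-patch history 20–1500 days before index; bupropion or
  varenicline 50/50 at 20–1500 days before index. Flags are
  independent, so overlapping attrition counts arise naturally.

What the generator does **not** simulate — and what passing tests
therefore cannot show about real data: quit outcomes (unobserved in
prescription records), over-the-counter NRT (invisible to GP data, a
known source of underestimated repeat use), prescription
quantity/duration, Read-code-level detail, seasonal prescribing, and
practice-level heterogeneity. Parameter-recovery tests demonstrate that
the pipeline measures what the generator encodes; they are not evidence
about any real population.

A separate hand-built toy fixture (13 patients) plants exactly one
patient per exclusion criterion, the 90/91-day boundary pair, a
pre-index combination, a three-type episode, and one
discontinued/one active patient, with shipped expected outputs
(`TOY_EXPECTATIONS`).

## Verification design

- Episode construction is checked against an independent straight-line
  gap-scanner oracle on 1,000 random instances (≤ 25 events, gaps
  1–400 days), plus idempotence and threshold-monotonicity properties.
- Cohort selection is re-checked by a brute-force six-criterion oracle
  written as plain date comparisons, over a 4,000-patient synthetic
  dataset; partition/conservation invariants tie the attrition rows
  together.
- Regimen classification is compared with an independent case analysis
  over all 127 non-empty class subsets.
- Reader/writer round-tripping is property-tested over generated
  datasets (Hypothesis, seeded).
- Distribution recovery runs at n = 20,000 (seed fixed): yearly
  combination shares within 3 percentage points, second-episode rate
  within 2 points, mean age within 0.5 years. These problem sizes keep
  the full suite under ~10 seconds while leaving binomial noise well
  inside the tolerances (at n ≈ 5,000 included patients a share of
  ~34% has a standard error of ~0.7 points).

`scripts/acceptance.py` additionally recomputes the analytic minimum
inter-episode gap (exhaustive scan of spacings 1–200 days) and the
headline proportions as arithmetic on published count tables fed
through the same reporting operations the pipeline uses on its own
outputs.

## Known limitations

Issue-date-only episodes understate treatment continuation when long
prescriptions are issued sparsely; age is year-precision; the cohort
logic deduplicates nothing across practices (a patient registered twice
would count twice); and the synthetic generator's attrition knobs are
independent Bernoulli flags, so it cannot represent correlated
exclusion patterns (e.g. young patients transferring out more often).
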