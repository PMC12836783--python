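# Methods

This note documents the models, rules and defaults behind `clinotext`, the
reasoning where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real clinical text.

## Extraction model

### Performance status

PS mentions are matched on aggressively normalized text: lowercase, all
whitespace removed, all punctuation except `.` and `,` removed (a keep-set
of letters, decimal digits, period and comma — so symbols, hyphens and
exotic numerals like `¼` all vanish).  The single pattern is

```
(keyword)(digit 0-5)(digit 0-5)?   with no digit following
```

with keywords `ecog`, `who`, `ps`, `performancestatus`, `performance`
(configurable).  Design points:

- **Two digits are a range, never a two-digit integer.** Hyphens are
  stripped by normalization, so "WHO 1-2" arrives as `who12` and is read
  as score 1 with secondary score 2.  A digit pair whose difference
  exceeds 2 is implausible as an ECOG range; the first digit is kept as
  the score and the second is discarded.
- **A trailing third digit vetoes the match** (`who58` matches nothing):
  a longer digit run is more likely a measurement than a PS.
- **Documented misses are preserved.** `WHO O` (letter O for zero)
  normalizes to `whoo` and cannot match; `PS is 2` normalizes to `psis2`
  and cannot match the strict pattern.  An optional relaxed pattern
  tolerating up to ~two short intervening words
  (`ps.allow_intervening_words`) ships **off**: in this setting silent
  false positives are worse than documented misses, and the strict/relaxed
  difference is itself informative (the relaxed run recovers the `psis2`
  class; see the pipeline tests).
- When a downstream consumer needs one value from a range, the first digit
  is used by default (clinicians usually write best–worst);
  `ps.range_policy: worst` selects the pessimistic end.

### Sentence segmentation

Clinical text marks sentence ends with newlines and wide whitespace at
least as often as with punctuation, so segmentation uses three explicit
rules: `.?!` followed by whitespace or end of text; any newline; a run of
≥3 spaces.  The 3-space threshold (not 2) avoids splitting on double
spaces left by manual edits and is configurable
(`tokenizer.min_space_run`).  A period between digits ("1.5 cm") is never
followed by whitespace and therefore never a boundary.  Period-bearing
abbreviations ("mg.") must be expanded *before* segmentation; the
abbreviation map runs in a single longest-first, left-to-right pass so
produced text is never re-expanded.

### Stop words and negation

Only the Dutch articles *de* and *het* are removable by default.  General
stop-word lists contain negation and hedging words ("no", "maybe") whose
removal would invert the meaning of progression sentences, so the
`StopwordPolicy` holds a protected negation lexicon and refuses, at
construction time, any removable word that appears in it.

### Phase classification

Sentences are labelled BP / PP / AP by prioritized regular-expression
rules; the engine itself does no negation scoping — *all* semantics live
in the rules, and a negated-progression BP rule (priority 100) simply
outranks the bare progression-keyword PP rule (priority 50).  Equal
priorities tie-break on lexicographically lowest rule id, so
classification is deterministic.  A synthesized AP rule (priority 90,
configurable) fires when a treatment-start word and a known
post-progression drug co-occur in a sentence: a next anticancer line
implies progression has occurred.  The shipped English and Dutch rule sets
are deliberately small starters; the n-gram and concordance tools exist so
deployments grow their own rules from their own corpus.

## Temporal resolution

- **Baseline PS**: closest mention in `[init − 30 d, init]`; if none, the
  earliest in `(init, init + 14 d]`.  Same-day ties: structured source
  beats mined, then the lower (better-documented-case) score, then input
  order.  Both windows are configurable.
- **Scan alignment**: a progression event called at a visit is moved to
  the latest scan within 14 days before it (scans typically precede the
  visit where their result is discussed).  The 14-day lag covers the
  "few days" of real documentation lag with margin; configurable.
- **Progression calling**: the earliest PP stands unless a BP follows
  within a 30-day confirmation window with no PP/AP re-assertion in
  between; a contradicted PP is abandoned and the next PP after the
  contradicting BP is tried; a cohort with PPs all contradicted but a
  later AP resolves to the AP (basis `ap_only`), as does a timeline with
  APs and no PP; only-BP timelines censor at the last BP; anything else
  (including empty timelines) is `unresolved` and goes to manual review.
  The confirmation rule is this package's formalization of "read the
  chronological overview and decide": progression assertions are sticky,
  but an immediate, uncontested walk-back is treated as a retraction.
- **Months**: `days / 30.44` (average Gregorian month).
- **Death dates** (optional table) count as progression events per the PFS
  definition, with basis `death`.  Default is no deaths table: inferring
  death from silence in the notes would be exactly the kind of incorrect
  assumption the pipeline is designed to avoid, so patients who die
  without documented progression surface as `no_follow_up`/manual review.

## Evaluation

- **PS metrics** are computed from the confusion matrix over patients
  present in both arms; precision of a class nobody predicted is defined
  as 0 (with a warning) so the weighted F1 stays a support-weighted mean.
  All P/R/F1 on the 0–100% scale.
- **Kaplan–Meier** uses lifelines' product-limit estimator; the median is
  where the step function first reaches ≤ 0.5, and its 95% CI inverts the
  pointwise log–log (Greenwood) band at 0.5.  All-censored samples report
  the median and CI as undefined rather than raising.
- **C-index** is Harrell's C with comparability decided on the *reference*
  arm only: a pair is comparable when the reference times differ and the
  shorter one ended in an event; text-mined times (censored or not) enter
  as recorded values, and text-mined ties count ½.  This choice treats the
  reference as the outcome and the text-mined time as the predictor; it is
  stated prominently because other censoring conventions exist and give
  different numbers.
- **Discrepancy flags**: ratio text-mined/reference > 3 or < 1/3, sorted
  by |log ratio|; a zero reference time yields an undefined ratio and an
  automatic flag.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the *structure* of an
oncology note stream, not its linguistic richness.

Defaults (the reference study conditions; all configurable):

| parameter | default | rationale |
|---|---|---|
| baseline PS distribution | 0.28/0.50/0.15/0.06/0.01/0 for PS 0–5 | mass on 0–2, as in advanced-NSCLC cohorts starting a next-line targeted agent |
| PFS distribution | exponential, median 8.0 months | single-digit-month medians typical of this setting; Weibull available |
| censoring | 13% + administrative cutoff at 28 months | realistic event-heavy follow-up |
| visit schedule | every 42 ± 10 days | routine oncology follow-up cadence |
| scan lead | 3–10 days before the progression visit | documentation lag between imaging and discussion |
| noise rates | all 0 | noise is opt-in per mode |

Each patient gets an initiation date, a latent baseline PS and a latent
progression time; the true progression date is the scan date, and the
progression *visit* (where the PP sentence appears) follows it by the scan
lead.  Visits before the scan render BP sentences; the first post-
progression visit renders a next-line drug start; a later one renders AP
follow-up language.  Every rendered PS mention is logged in a ledger with
its adversarial mode, making the generator bookkeeping — not expectation —
the oracle for extraction tests.

**Censoring is independent of the event process.** The configured
censoring probability is realized through an exponential censoring time
whose rate is calibrated (closed-form for exponential events, numerically
for Weibull) so that `P(censor before event)` equals the configured value;
the administrative cutoff is likewise independent.  A scheme that first
flips a coin and then places the censor time inside the event time would
make censoring informative and bias the Kaplan–Meier estimate by
construction; with independent censoring the coverage of the KM median CI
is a meaningful calibration check (empirically ~94–98% over 50 replicates
at n = 300).

Noise modes reproduce documented real-world failure shapes: `WHO O`
(`p_misspell_zero`, applies to true PS 0), `PS is 2` (`p_intervening`),
vague progression wording that names no progression keyword and therefore
exercises the delayed/`ap_only` pathway (`p_vague_progression`), drug
shorthand (`p_abbrev`), and undocumented PS (`p_missing_ps_mention`).
These modes cause **misses, never false values** — which is exactly the
degradation profile the tests assert (recall drops, precision stays 100%).

### What passing the synthetic benchmark does *not* show

Template-rendered sentences are a tiny, closed language: perfect zero-noise
recovery demonstrates that the plumbing (normalization → segmentation →
rules → temporal resolution → statistics) is correct, not that the starter
lexicons cover real Dutch or English clinical prose.  Real notes contain
spelling errors (out of scope by design), institution-specific templates,
copy-paste artifacts, and progression described only in attachments —
none of which the generator emulates.  Published performance figures from
real EMR cohorts cannot be reproduced from synthetic data and are not
targets of this package's tests.

## Numerical and degenerate-input choices

- Problem sizes in the test suite and acceptance script (300-patient
  end-to-end runs, 50 replicates for CI coverage, 150 patients per noise
  level) were chosen as the smallest sizes at which the stochastic checks
  are stable across seeds.
- Dates are whole days; months are `days / 30.44`.
- Ambiguous day/month literals under `auto` dialect are resolved by the
  configured day-first preference and *flagged*, never silently guessed;
  unparseable rows go to a rejects table.
- Empty inputs: empty note file → empty corpus with a warning; empty
  treatment table → the pipelines refuse (no cohort); all-censored KM →
  undefined median; < 2 comparable pairs → undefined C with a warning.
- Determinism: same corpus + config give byte-identical extraction tables;
  the generator is fully reproducible from its seed, including the
  rendered text.
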