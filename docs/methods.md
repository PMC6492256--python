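# Methods

`morphocomplex` analyzes miniature-artificial-language data bearing on a
question from the cultural evolution of language: do adult learners simplify
redundant inflectional morphology, and can their simplifications spread
through subsequent learning or through accommodation in interaction?  The
package implements the measurement machinery (scoring, a model-selection
complexity statistic, input mixing, a dyad simulator) and a synthetic-data
generator that stands in for human participants.

## Languages and scenes

A scene is a meaning triple (number, animal, motion).  The 18-scene learning
language describes each scene with a quantifier, noun, and verb, each a stem
plus suffix.  Suffixes redundantly mark number and do so irregularly: the
quantifier uses *-a/-ak* except *-u/-uk* for the crocodile; the noun plural
*-op* is dropped for the bird; verbs take *-an/-asp* (*-en/-esp* for the
crocodile) and every plural looping scene takes *-onk*.  Stored forms are
unhyphenated strings with a separate stem/suffix index per entry, so
presentation hyphens never leak into distances.

The 9-scene interaction languages pair one of three nouns (*kwako*, *grolo*,
*snapo* — the bird is replaced by a dog here) with a verb.  Three of five
verb forms are drawn at random as regulars for the three motions; the other
two are placed as irregulars in two cells sharing no animal and no motion.
There are 18 such placements and P(5,3) × 2 × 18 = 2160 distinct languages;
the two irregular forms are assigned to the two cells in random order (the
order is not pinned down by the design; randomizing it affects only which
form lands where, not any statistic).  Generation is driven by a single
integer seed with a named generator version recorded in the spec metadata.

## Scoring

Produced words are segmented automatically: if a target stem is an exact
prefix the word splits there (longest stem on ties); otherwise the split
point and stem minimizing the edit distance between the word's prefix and
any candidate stem are chosen deterministically (ties: longer stem, then
lexicographic stem, then longer prefix) and the record is flagged for
review.  This replaces hand-coding of non-prefix cases with a reproducible
rule plus an audit flag.  Zero-marked suffixes are coded `NULL` and scored
as the empty string.

Accuracy is 1 minus the normalized Levenshtein distance, where the
normalizer is the length of the longer string and the distance of two empty
strings is defined as 0.  Unit-cost edit distance is computed by `edlib`;
tests check it exhaustively against a bottom-up evaluation of the recursive
definition for all pairs up to length 6 over a 3-letter alphabet.
Aggregation averages within participant × round first, then across
participants; CIs are on the mean of means, t-based below 30 participants
(the CI method is not otherwise pinned down), with width 0 for a single
participant (degenerate, by convention).  Missing words score 0 on both stem
and suffix rather than being dropped — conservative, and no dropped-item
rule exists to mirror.

## Conditioning complexity

The central statistic asks how many semantic features a learner's suffix
choice is conditioned on.  For one participant × word class × round (one
suffix observation per scene), every multinomial-logit model predicting the
suffix category from scene features is fitted and the lowest-AIC model
selected; the complexity score is the number of distinct features in the
winner (0–3).

The candidate predictor set contains the full and collapsed codings of each
feature: Number only its 2-way contrast; Animal and Motion their 3-way
contrast plus the three one-vs-rest binarizations (4 variants each).  A
model includes at most one variant per feature — a collapse is nested in the
full coding, so co-inclusion is collinear and the reported winning formulas
never co-include.  The space is all 2 × 5 × 5 = 50 additive combinations
(including intercept-only), plus the full-factorial augmentation of each of
the 40 selections with ≥ 2 variants: 90 models.  The exact interaction
scheme in the original procedure is not fully specified; full-factorial
augmentation is the interpretive choice here, and it cannot change the
worked-example surface because all its winners are additive.

Fitting is plain maximum likelihood (reference-category parameterization)
by BFGS with analytic gradients, a hard cap of 100 iterations, and stopping
when the relative log-likelihood change falls below 1e-8.  Under complete
separation the likelihood approaches 0 and the capped iteration leaves it
there; this mirrors the conventional capped-iteration multinomial fitters,
keeping AIC values under separation comparable.  An optional ridge penalty
(off by default) is exposed for degenerate inputs.  Parameters are counted
as k = (C − 1)(1 + m) for C outcome categories and m slope columns; a
single-category outcome is scored loglik 0, k 0, making intercept-only AIC
well-defined.  AIC ties within 1e-9 break to fewer parameters, then
canonical model order (feature count, column count, formula).  Any phase can
be scored; the round-2 vs round-8 contrast is a reporting convention.

Suffix entropy is the Shannon token entropy (bits) of the empirical suffix
distribution within a word class; token weighting and log base 2 are
conventions adopted here.

## Synthetic learners

Simulated learners are phenomenological: a grammar plus noise, not a
learning model — the pipeline needs data with a known conditioning
structure, not a theory of acquisition.  Each learner's grammar conditions
each word class's suffix on a configured feature subset, with idiosyncratic
form-to-cell assignment, a zero-marking probability (default 0.05 at early
rounds, the observed early-learning rate), and per-character edit noise.

Identifiability shapes the generator: for ≤ 2 conditioning features each
conditioning cell gets a distinct form (drawn from the target's inventory
for that class, topped up with novel forms), which makes the injected
partition exactly recoverable by AIC.  For 3-feature conditioning a
distinct-form-per-scene system would be a saturated 18-category paradigm
that AIC scores *below* intercept-only — indistinguishable from noise — so
the generator instead emits a paradigm with the target verb system's shape
(a marked number, a special animal with its own forms, a special motion
override) with levels and forms drawn idiosyncratically.  This mirrors how
three-feature conditioning actually appears in such data: as target-like
patterned systems, not as 18 unrelated forms.

The default cohort schedule has learners condition on one feature with
noisy stems at rounds 1–2, two features mid-training, and reproduce the
target exactly from round 6 — an idealization of the observed trajectory
(stems near ceiling early, suffixes approaching ceiling late).  What
passing tests show is that the pipeline measures injected structure
correctly; they do not show anything about human learning curves, which the
generator only caricatures.

## Input mixing

Source speakers are those whose round-2 stem productions exactly match the
target for ≥ 90% of labels.  A training phase for a second-generation
learner samples 9 of the 18 scenes without replacement and divides them
across sources with counts {5, 4} (two sources) or {2, 1×7} (eight sources,
double-contributor uniform), pairing each scene with that source's
description from the relevant round (round 8 for complex sources, round 2
for the simplified half in mixed conditions); phases resample
independently.

## Dyadic interaction

Agents know their assigned grammar (training-to-criterion is abstracted
away, as is the 10-cycle exclusion rule).  In mixed dyads the simple agent
saw only the seven regular pairings and regularizes the two irregular cells.
Each round, the two agents alternate single director trials, each directing
all 9 scenes per round in random order, for 3 rounds, then produce all 9
scenes solo.

Accommodation is a per-cell state machine for the complex speaker: once
exposed to the partner's regularized form for a cell, they adopt it with
probability q at each subsequent opportunity for that cell; after adopting
they persist with probability 21/22 per opportunity (a failure reverts the
cell for good).  Matching succeeds with 0.97 for forms in the matcher's
grammar and 0.5 for an unknown irregular form (a modeling choice standing
in for partial inference from the recognized noun).

The default q = 0.411 is calibrated analytically, before any simulation,
from the observed count of complex speakers ever regularizing (29 of 40
cases over three rounds): with exposure preceding the speaker's first
opportunity in about half the cases, 0.5[1 − (1−q)³] + 0.5[1 − (1−q)²] =
29/40 gives q ≈ 0.411.  The observed "27 of 29 first regularizations
followed exposure" is a precedence diagnostic, not an adoption rate; in
this simulator precedence is structural (exposure is the only adoption
channel) and is asserted as an invariant.  At these defaults the simulator
produces a complex-speaker regularization proportion near one half of
irregular trials, rising over rounds.  The solo post-test reproduces the
agent's current state; no separate retention decay is modeled, so synthetic
post-test regularization is higher than in human dyads, where interaction
gains partly washed out before the solo test.

## Descriptive statistics

The post-test 2×2 (dyad type × any-regularized) uses the Pearson chi-square
without continuity correction — χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)) —
because the reported 5.626 matches the uncorrected statistic (5.625) to
rounding and not the corrected one (≈ 3.9); the residual 0.001 is treated
as print rounding.  Zero margins raise rather than return an undefined
statistic.  All other condition comparisons are reported as estimates with
CIs (Wilson intervals for proportions), not p-values.  Group-level
inferential mixed-effects models are deliberately out of scope: the
pipeline emits tidy tables suitable for external refitting rather than
re-estimating coefficients that depend on the original human data.

## Problem sizes and determinism

Default runs use 26 simulated learners × 8 rounds, 10 complex + 20 mixed
dyads, and 90 model fits per complexity score (≈ 0.4 s per score); the
property suites use 100 recovery seeds and 200 dyad replicates.  Every
simulator is driven by explicit integer seeds through `numpy`'s seed-
sequence spawning, and pipeline outputs are written with fixed float
formatting, so identical inputs, config, and seed give byte-identical
outputs.

## Known limitations

- The simulators reproduce the *structure* of the study data, not human
  variability: learner noise is i.i.d. character noise, and accommodation
  is a two-parameter state machine.
- The best-edit segmentation fallback is deterministic but can differ from
  a human coder on badly mangled words; such records carry a review flag.
- Under complete separation, reported log-likelihoods depend on the capped
  optimizer path; AIC comparisons are meaningful within this convention
  but the absolute values near zero are not ML estimates in the limit.
- The matcher model for unknown forms is a single success probability; it
  does not model scene-array elimination explicitly.
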