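# Methods

## Problem and design

The package recovers a binary patient-level phenotype — "has served in the
armed forces for at least one day" — from free-text clinical notes, in a
setting with no structured service marker. Two classifiers are chained.
The keyword rule stage is transparent and auditable; the learned stage adds
lexical generalization but is constrained by a rule-based gate so that a
positive call always rests on an explicit military phrase. The design
assumption throughout is asymmetric: false positives (non-veterans swept
into a veteran cohort) are considered more damaging than false negatives,
which motivates the gate, the confounder suppression, and the conservative
defaults below.

## Text normalization and matching

All matching happens on a single normal form: lowercase, every character
that is not a letter/digit/whitespace replaced by a space (underscore
included), whitespace collapsed. Offsets are 0-based half-open character
positions in this normal form; original-text offsets are not tracked.
Matches are token-boundary aligned ("soldiering" never matches "soldier").
When several lexicon entries match at one starting token the longest wins;
matches at different starts may overlap, which is what lets a confounder
span strictly contain a military span.

Confounder handling is containment suppression: a military match carries no
evidence if its span lies inside a confounder match ("army" inside
"salvation army"). Sentence-level exclusion was rejected as too blunt — the
canonical confounders are strict superstrings of military terms, so span
containment is both necessary and sufficient for them.

## Other-person attribution (preprocessing step 2)

The mechanism is a symmetric token-window co-occurrence rule: a military
match with a relation-lexicon match (kinship vocabulary: "father",
"husband", ...) separated by fewer than `relation_window` tokens (default 5)
is deleted together with the relation word. The window and both lexicons
are configuration. A windowed rule is the simplest mechanism that removes
the documented family-member failure mode; whether phrase-, sentence- or
document-scope attribution is more faithful to real note language is an
open question, and the window is exposed precisely so it can be tuned.

## Stop/frequent-word removal (step 3)

Corpus document frequency is computed in a first pass; tokens in the
stop-word list (a packaged standard English list, overridable) or with df
above `frequent_term_threshold` (default 0.85) are dropped — except any
token occurring inside a military lexicon entry, which is always retained
whatever its frequency. The threshold default is a deliberate free
parameter: no principled value exists without the target corpus, so it is
set high enough to touch only boilerplate vocabulary.

## Learned stage

TF-IDF uses the smoothed-idf dialect idf(t) = ln((1+N)/(1+df(t))) + 1 with
L2-normalized rows over unigrams and bigrams of the preprocessed token
streams. The classifier is logistic regression (liblinear, C = 1.0,
balanced class weights) thresholded at 0.5 on the predicted probability.
Balanced class weights matter: disclosing notes are a small minority of
documents, and without reweighting the regularized probabilities shrink
toward the base rate and the fixed 0.5 threshold under-calls positives on
small corpora. Empty documents predict 0 by definition rather than passing
through the model — an empty note cannot evidence service. All randomness
sits behind one integer seed; training is deterministic given seed, config
and data, and a saved model (joblib bundle of vectorizer + classifier +
config) reproduces its predictions exactly after reload.

The postprocessing gate re-runs the evidence check (normalization +
confounder suppression, without attribution removal) on the raw document
text of every ML positive and flips unsupported positives to 0. Negatives
are never promoted, so gating can only shrink the positive set.

## Aggregation and evaluation

Patient label = OR over document labels, with document and positive-document
counts retained. Aggregation is order-invariant (output sorted by patient
id) and idempotent.

The 2×2 table is stored as a = (tool 0, true 0), b = (tool 0, true 1),
c = (tool 1, true 0), d = (tool 1, true 1). Two conventions are computed and
always labeled: the *study* convention reads detection of non-veterans as
sensitivity (a/(a+c)) and recovery of veterans as specificity (d/(b+d)); the
*veteran-positive* convention is the usual epidemiological one and is the
exact swap. The Youden index J = sens + spec − 1 is identical under both.
Percent agreement (a+d)/n and J are distinct named quantities and are never
conflated — on the 146-patient validation table they differ materially
(0.8356, printed 83.6%, versus J = 0.745). Any statistic with a zero
denominator is reported as undefined (None), never as 0. Wilson confidence
intervals were considered and left out: the evaluation layer mirrors a
single external survey comparison, not an inference framework.

Cohort-flow reporting gives 100·count_out/count_in per stage at 1 dp, with
zero-denominator stages undefined. The eligibility screen applies seven
criteria in a fixed order (alive; age ≥ 18; consent; no dementia/psychosis
indicator; contactable; English without interpreter; coordinator approval
when active). A missing attribute fails its criterion — conservative
exclusion, matching a recruitment process that drops uncertain cases.
"Active patient" is consumed as an explicit boolean flag because no
operational definition is available to infer it from.

## Synthetic corpus

The generator emulates the statistical skeleton the pipeline assumes, not
clinical language. Notes are 2–4 neutral psychiatric filler sentences from
plain-text templates, plus optional planted sentences: self-service
disclosures (military-lexicon phrases; veterans only, per-note probability
`p_disclosure` = 0.6), other-person service (relation word within the
attribution window of a military phrase; per-note probability 0.15),
Salvation Army mentions (0.10) and military metaphors (0.10). Confounders
are injected into non-veteran notes by default (overridable), mirroring the
observation that they drive false positives. Veteran prevalence defaults to
0.233 — the proportion of the validation sample classified as veterans —
and the default corpus is 400 patients × 3–7 notes ≈ 2000 documents.
Sub-streams are derived per patient by SHA-256 hashing of (seed,
patient_id), so corpora are byte-identical across runs and locally stable
under edits.

Templates and lexicons are co-designed and this is load-bearing: every
disclosing note is guaranteed to carry surviving military evidence, filler
avoids military/relation/confounder tokens entirely, and metaphors avoid
exact lexicon tokens. Consequently the synthetic task is near-separable.
Passing tests therefore demonstrate the mechanics — matching, attribution,
suppression, gating, aggregation, statistics — not performance on real
clinical text, where vocabulary drift, misspellings, negation ("denies ever
serving") and non-template phrasings all occur and none are modeled.
Negation handling in particular is an explicit non-goal.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 400-patient corpus (≈2000
documents) for end-to-end checks, ≥500 notes for the rule-vs-oracle
comparison, ≥1000 for gate monotonicity, and exhaustive enumeration of all
2×2 tables with n ≤ 20 for the metric identities; these sizes give the
properties being checked no room to pass by luck while keeping the whole
suite near-instant. Stored statistics are never rounded; rounding (2 dp for
proportions, 1 dp for percentages) happens only in presentation. Ties at
the 0.5 decision threshold count as positive (≥). Known limitations beyond
the synthetic/real gap: the shipped military lexicon is a best-effort
vocabulary, not a validated gold standard; attribution scope is a windowed
stand-in; and document-level training labels must be supplied (here by the
generator) — the package does not bootstrap its own annotations.
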