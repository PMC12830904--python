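# Methods

This note documents the models, conventions and design choices behind
`vftk`, in the spirit of a statistical software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. Transcript model

A session holds two 60 s subtasks (phonemic: words starting with 'l';
semantic: animal naming). Each subtask carries an optional manual
*reference* transcript and automatic transcripts at three levels:

* **U** — unprocessed ASR output;
* **F** — filtered: fillers, asides and off-task speech removed.
  Filtering only removes, so `|F| ≤ |U|`;
* **A** — adjusted: clearly misrecognized words corrected *in place*
  (count-preserving, `|A| = |F|`), while out-of-lexicon forms at edit
  distance ≥ 2 are preserved as potential neologisms.

Token text is normalized to lowercase, punctuation-stripped, NFC unicode
(so Slovene diacritics compare consistently in edit distances). Times
are subtask-relative seconds, serialized at millisecond precision.
Bundles are one JSON document per session plus a timestamp CSV
(`subject_id,task,start_s,end_s`), mirroring the paired
audio-plus-metadata layout of field recordings.

## 2. Word alignment and WAcc

Word accuracy is `1 − (S + D + I)/N` under a unit-cost
substitution/deletion/insertion alignment (no transpositions), with a
deterministic traceback tie-break (match > substitution > deletion >
insertion). WAcc is not clipped at zero: insertion-heavy hypotheses can
score negatively, and downstream consumers must accept that. By default
a subject's WAcc concatenates both subtasks into a single pair; per-task
scoring is an option. The alignment cost is verified in the test suite
against exhaustive recursion (all 2-symbol pairs up to length 6) and
against an independent alignment library.

## 3. Mock annotation provider

The refinement and tagging stages define a provider contract so a remote
LLM can be dropped in; the shipped provider is deterministic and
lexicon-backed, which keeps the pipeline reproducible offline:

* **Filter (U→F):** drop tokens in the filler lexicon.
* **Adjust (F→A):** replace a token at edit distance exactly 1 from a
  known word with that word — candidates from the task lexicon first
  (the annotator knows the task context), then the general lexicon, with
  a lexicographic tie-break. Distance ≥ 2 tokens are preserved.
* **Tagging:** semantic-task intrusion ⇔ a known word outside the animal
  lexicon; phonemic-task intrusion ⇔ a known word not starting with the
  target letter; neologism ⇔ absent from every lexicon; stilted ⇔ in the
  formal/archaic register list. Flags are per-token, hence idempotent
  and order-independent. Provider outputs are validated (a neologism
  claim for an in-lexicon word is rejected).

The packaged toy lexicons (~170 animals, ~155 'l'-words, 30 fillers,
40 off-task nouns, 20 formal-register words) are Slovene or
Slovene-like; "stilted" has no standard operational definition, so the
formal-register list is an explicit stand-in. Rate tables (retention,
F-vs-A overlap, intrusion/neologism shares) are token-weighted pooled by
default, with per-subject averaging as an option, and are computed on
A-level tokens because tagging follows refinement in the pipeline order.

## 4. Feature roster (58 entries)

Fixed anchor slots: V1 semantic phrase rate; V3 semantic maximum-gap
fraction; V4 semantic minimum gap; V16 phonemic phrase rate; V23/V26
max/kurtosis of consecutive semantic similarity; V27/V30 mean/min
consecutive phonemic (Levenshtein) similarity; V39 similarity of the
joined F and A transcripts. The remaining slots follow a documented
summary-statistic scheme (`vftk.features.FEATURE_SPEC`): per-task gap
series statistics as fractions of duration — the gap series includes
leading and trailing silences, so late-task silence registers as a long
maximum pause — token-duration statistics, similarity-series statistics,
and per-flag annotation proportions. V38 is the corrected-token
fraction. N1–N17 are prosodic and voice-quality descriptors ingested
from an acoustic table or computed by `vftk.acoustics` (autocorrelation
F0 tracker; semitones re 27.5 Hz; per-voiced-segment least-squares
slopes; 80th−20th percentile F0 range; jitter, shimmer in dB, PPQ5 —
standard acoustic-parameter-set conventions, not field-specific facts).
AGE and GENDER (female = 1) complete the vector.

Conventions: kurtosis is Fisher excess kurtosis with population moments,
0 by convention for zero-variance series; feature-internal SDs are
population SDs; Z-scoring uses sample SDs (ddof = 1). Degenerate inputs
(< 2 tokens for a similarity series, no voiced frames, missing acoustic
entries) are imputed with 0 and flagged; downstream Z-scoring keeps the
imputed value uninformative. Features default to the A level; U, F or
the reference transcript are selectable (parameter-recovery tests use
the reference level, where the generator's latent truth is defined).

## 5. Bayesian group comparison

Each group's feature sample is modeled with a normal likelihood and a
weakly-informative conjugate normal-scaled-inverse-χ² prior
(κ₀ = ν₀ = 10⁻³, prior location at the sample mean, prior scale at the
sample variance — with these near-zero weights the data dominate).
Sampling is exact: σ² from its scaled-inverse-χ² conditional, μ | σ²
from its normal conditional. Defaults: M = 20,000 draws, chosen so the
binomial Monte-Carlo SE of p̂_r is ≤ 0.0035 at p = 0.5, consistent with
reporting ±0.01. The 95% HDI is found by sorted-window search (valid for
the unimodal posteriors produced here; cross-checked against an
independent implementation in the tests). p̂_μ is the fraction of paired
posterior draws with μ_h > μ_s; p̂_r draws one posterior-predictive
observation per group per draw and counts pairwise wins, with binomial
SE. DD = |p̂_r − ½| ranks features (stable tie-break by feature id). A
heavy-tailed posterior-predictive variant is available behind the same
interface as a sensitivity hook. A zero-variance sample is jittered
(with a warning) to keep the posterior proper.

## 6. Additive boosting classifier

`AdditiveBoostingClassifier` is a scikit-learn estimator implementing a
boosted generalized additive model with no interaction terms. Features
are pre-binned on training quantiles (default ≤ 32 bins). Training makes
`n_passes` cyclic passes over the features; each visit fits one
single-feature tree (≤ 3 leaves, greedy gain-based splits on the binned
axis, Newton leaf values clipped to ±4, ridge λ = 10⁻³ in the gain) to
the current logistic gradient and accumulates `learning_rate` times its
output into that feature's piecewise-constant shape. β₀ starts at
logit(prevalence); after training each shape's training-set mean is
folded into β₀, so contributions read as deviations from the average
subject. Prediction clips logits at ±30 before the sigmoid. Defaults are
learning rate 0.1 with 300 passes — the same total shrinkage budget as a
slower schedule (0.01 × 3000) at a tenth of the fits, chosen so the full
leave-one-out protocol at n = 126 with 58 features remains interactive;
the inner loop is JIT-compiled when numba is available, with an
identical pure-numpy fallback. A single-class training set yields the
documented degenerate model (zero shapes, clipped intercept).

Explanations are exact by construction: the logit is β₀ plus the sum of
per-feature contributions (asserted to machine precision in the tests);
global importance is the mean absolute contribution; local explanations
rank signed contributions, with the top 10 plotted.

## 7. Evaluation protocol

Leave-one-out cross-validation: for each subject, Z-score parameters are
fit on the remaining n−1 rows only, the learner is cloned and fit, and
the held-out P(patient) is recorded; pooled held-out probabilities are
scored at the fixed 0.5 threshold (CA, SEN, SPE, PPV, F1) plus a
tie-aware midrank AUC. Fold-local normalization is the default because
fitting the scaler on all rows would leak the held-out subject; a global
option is retained for sensitivity analysis. Baseline learners (Gaussian
naive Bayes, L1/L2 logistic regression, random forest, SVC, gradient
boosted trees) are registry adapters around standard implementations at
their default settings and run in the identical harness.

## 8. Synthetic cohort generator

The generator emulates the *study conditions* of a two-group clinical
verbal-fluency corpus (68 controls, 58 patients). Group parameters are
anchored to published group-level summaries frozen in
`vftk.calibration`: word-production rates and the semantic maximum-gap
fraction (group SDs back-derived from the HDIs of posterior means as
sd = half-width/1.96·√n), automated intrusion/neologism percentages,
refinement retention and overlap rates, per-level word-accuracy means,
and three anchored acoustic slope descriptors. Where no value is
published, defaults are artifact choices made once: distribution
families (lognormal for rates so configured means hold in expectation;
beta for the long-pause fraction; lognormal gap body with σ = 0.7),
token durations (0.45 ± 0.08 s), phonemic long-pause targets, clustering
(most-similar next word), derailment (least-similar next word) and a
coherence floor that separates the groups' consecutive-similarity
profiles, and the remaining acoustic descriptors with modest group
separation.

Timing model per subtask: n words (n/60 lognormal at the group rate),
truncated-normal durations, and n+1 silent gaps (leading, inter-word,
trailing) from a lognormal body plus one designated long pause whose
duration fraction is a beta draw at the group's maximum-gap target;
gaps are rescaled to exactly fill the 60 s window. ASR corruption is
per-token: deletion, substitution (a random character edit, distance 2
with probability 0.15), and filler insertion with interpolated
timestamps; F and A levels are derived by the pipeline's own mock
refinement, so the generated levels obey exactly the contracts the
downstream stages assume. Every subject's latent draws (realized rates,
maximum-gap fractions, injected error counts, acoustic values) are
stored as truth for recovery tests.

**What passing tests do and do not show.** The generator reproduces the
calibrated rates in expectation, the published directional group
patterns, and the U < F ≤ A word-accuracy ordering; recovery tests
confirm the measurement pipeline returns what was injected. It does not
emulate real lexical statistics, semantic embeddings, medication or
symptom-severity effects, recording-channel confounds, or the coupling
the published summaries imply between correction volume and accuracy
gain — a per-token independent corruption model cannot match retention,
overlap and the small F→A accuracy gain simultaneously, so corruption
defaults favor the retention and corrected-fraction targets. Group
contrasts are consequently cleaner than clinical reality: classifier
metrics near 1.0 on synthetic cohorts validate the pipeline's mechanics
and say nothing about clinical accuracy.

## 9. Known limitations

* The Bayesian model family (normal likelihood, conjugate prior) is the
  package's own choice; the analysis it emulates did not publish its
  likelihood, prior or sampler.
* The semantic-similarity provider defaults to a character-bigram
  cosine — deterministic and offline, but not a semantic embedding; it
  is pluggable.
* "Stilted" tagging is operationalized as membership in a small
  formal-register list.
* The acoustic path computes simplified named descriptors, not a full
  standardized parameter set; ingestion of externally computed tables is
  the primary route.
* Whether demographics enter the V and N feature sets individually is
  configuration (`include_demographics`); the default includes them only
  in the combined set.
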