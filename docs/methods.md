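# Methods

## Problem and unit of analysis

The unit of classification is one pediatric (ages 6–17) emergency
encounter. The target is a binary label: whether the encounter involved
self-injurious thoughts and behaviors (SITB) — suicidal ideation, suicide
attempt, preparatory acts, or nonsuicidal self-injury. The scientific
question is comparative: how well do different electronic-health-record
representations of the same encounter (structured fields only, note text
only, or both) support detection, and how uniformly across demographic
and diagnostic subgroups.

## Synthetic cohort generator

No public corpus of labeled pediatric mental-health ED encounters exists;
clinical text of this kind cannot be deposited. The generator therefore
emulates the *statistical structure* that drives the comparison, not
clinical language itself.

Mechanism, per encounter:

1. A demographic stratum is drawn from `subgroup_spec`, and the SITB
   label from the configured prevalence (default 0.46). Default strata
   are sex × age-group cells matching 51.3% female and 26.4% children.
2. **Structured documentation** of a true-SITB encounter is governed by
   the stratum's `structured_fidelity` — the probability that each
   structured SITB indicator (ICD-coded diagnosis, SITB chief concern,
   positive c-SSRS screen) is actually recorded. Defaults grade downward
   from female adolescents (0.90) to male children (0.48), and are
   further multiplied down when neurodevelopmental / psychotic /
   externalizing diagnostic categories are present (e.g. ×0.60 for
   intellectual disability). This single mechanism — true cases whose
   structured footprint silently vanishes for particular strata — is
   what produces subgroup detection gaps downstream.
3. **Narrative documentation** is governed by `text_fidelity` (default
   0.95 for every stratum, deliberately uniform and higher than any
   structured fidelity): with that probability, a true-SITB encounter's
   notes contain at least one sentence affirming current, patient-own
   SITB. Any encounter may additionally receive *distractor* sentences
   (rate 0.35) — SITB-lexicon phrases carrying a negation ("denies
   suicidal ideation"), historical ("history of self-harm last year"),
   or other-subject ("a classmate endorsed…") modifier — so negative
   encounters are lexically contaminated but never fully affirmed. The
   four annotation axes (SITB-related, affirmed, present-tense,
   patient-referent) are carried as per-sentence truth tags; a sentence
   counts as SITB evidence only when all four are true.
4. The **c-SSRS screen** is administered with probability 0.70; items are
   asked sequentially and administration stops at the first non-positive
   response (the stopping negative is observed; everything after it is
   missing). Non-administration leaves all items missing. Auxiliary
   fields (psychotropic medications, homicidal-ideation screen,
   overdose labs, disposition, prior utilization, SVI/ADI) carry
   label-dependent rates calibrated to published sample marginals
   (e.g. ~28% psychiatric hospitalization, ~18% SITB chief concerns).
   Non-gatekept variables are missing completely at random at 5%
   (insurance 30%).

Determinism: every draw flows through one `numpy` generator seeded from
the config; identical (config, seed) reproduces byte-identical cohorts.

What the generator does **not** model: realistic clinical prose beyond
the tag taxonomy, within-patient visit sequences (one visit per child),
census-tract geography, and any joint demographic × diagnosis ×
prevalence structure beyond the marginals — published tables give
marginals only, so defaults are marginal-matching with independence
elsewhere. Consequently, passing tests show that the *pipeline* recovers
the planted structure (ordering of modalities, gap reduction), not that
any particular accuracy level would transfer to real notes.

## Text-scoring chains

**kNN sentence chain.** Sentences are segmented (rule-based: terminal
punctuation or newlines; concatenation reconstructs the input modulo
whitespace), embedded, and scored as the mean label of their K=5 nearest
neighbors in a labeled development pool, with angular distance
d = √(2 − 2·cos) on L2-normalized vectors; the encounter score is the
mean over its sentences (0 with a no-text flag when there are none).
Distance ties are broken by pool insertion order. The same chain runs
under two embedding backends.

**Embedding backends.** The defaults are deterministic hashed
bag-of-token vectors (signed hashing, L2-normalized): a general backend
(256 dims, unigrams) and a "medical" variant (384 dims, unigrams +
bigrams). They are genuine sentence embeddings for the synthetic
vocabulary and keep the repository fully offline and reproducible;
pretrained sentence encoders plug in behind the same
`EmbeddingBackend` interface for use on real text.

**Neighbor index.** Exact mode is blocked brute-force search (the
reference semantics). Approximate mode is a forest of random-projection
trees (hyperplanes through the midpoint of two random members; leaf
candidates from all trees are exact-ranked), trading recall for speed on
large pools. Tests bound the approximate-vs-exact score discrepancy.

**Likert note chain.** Each note receives an integer score from −3
(definitely no SITB) to +3 (definitely SITB); the encounter score is the
maximum over parseable notes (scale minimum plus an unscorable flag when
none parse). Scoring a note with a large language model is represented
by (a) a parsing contract — an embedded JSON object with an integer
`score` in [−3, 3] and optional `rationale`; anything malformed is
flagged, never raised, and excluded from the max without retry — and
(b) a deterministic lexicon/ladder scorer used throughout: +3 for an
affirmed present-tense patient-referent lexicon hit, +1 historical-only,
−1 other-referent, −2 negated, −3 no hit, with cue precedence
negation > other-subject > historical, and note score = max over
sentences. The ladder is the package's own construction for offline
testing, not a claim about any model's behavior.

## Feature sets

Ten design matrices per cohort: `ICD_CC` (3 columns), `CSSRS_ICD_CC`
(+5 c-SSRS items × value/missing-indicator pairs, 13), `MHDX_ICD_CC`
(+17 diagnostic categories, 20), `ACS` (all structured fields, 67),
three single-column text sets, and three hybrids (ACS ⧺ one score
column). Encoding rules: c-SSRS positive→1 with a paired missing
indicator preserving the gatekeeping pattern; the same value-0 +
indicator rule for missing numerics (SVI, ADI); categoricals one-hot
with an explicit `unknown` level; count variables untransformed (tree
ensembles are monotone-invariant). Every column carries a provenance tag
(`structured` / `missing-indicator` / `text-score`) written to a sidecar
manifest.

## Validation protocol

Per feature set: stratified 10-fold outer cross-validation. Within each
outer fold the training portion is split 50/50 once (stratified); every
point of the hyperparameter grid (default: 100 trees, depth ∈ {8, ∞}) is
fit on one half and scored by plain accuracy at the 0.5 probability
threshold on the other; the winner (ties → grid declaration order) is
refit on the full outer-training portion and predicts the held-out fold.
Folds select hyperparameters independently. Stratification of the outer
folds is a robustness choice for small synthetic cohorts; at ~46%
prevalence it is immaterial for large ones. The inner "50/50 split" is
implemented as a single split rather than 2-fold CV — the protocol
description is ambiguous on this point and the single split is the
cheaper faithful reading.

The development pool (default 19% of encounters, mirroring a 724/3828
hold-out) is removed before any classifier training and supplies only
the labeled sentences for the kNN indices; an id audit asserts no
development encounter ever enters a CV fold.

## Statistical evaluation

- **AUROC** is the Mann–Whitney concordance probability with ½ credit
  for ties (cross-checked in tests against an all-pairs enumeration).
- **Paired DeLong tests** use the structural-components covariance
  estimator with a two-sided normal reference; degenerate variance
  (identical scores) reports z = 0, p = 1. The implementation is
  cross-checked against a 20,000-replicate paired exchangeability
  permutation (randomly swapping the two score vectors per subject) and
  against an independent reference implementation.
- **Cross-fold confidence intervals** are mean ± q·sd/√folds. The
  multiplier defaults to the t quantile (df = folds − 1): in a coverage
  simulation against a known generative AUROC (binormal scores,
  Φ(μ/√2)), the normal quantile covers only ~90% at 10 folds while the
  t quantile restores ~95%; the normal multiplier remains available.
  Overall AUROC CIs use cross-fold variability; subgroup CIs use the
  single-sample DeLong analytic variance on pooled out-of-fold
  predictions (fold-wise subgroup counts are too small to support
  cross-fold intervals).
- **Mean ROC curves** linearly interpolate fold curves onto a uniform
  101-point false-positive-rate grid, average the true-positive rates,
  and pin the endpoints at (0,0) and (1,1).
- **Permutation importance** is the mean metric drop over within-column
  shuffles, computed on held-out data: evaluated on training rows, a
  deep forest's memorization of even a pure-noise column yields
  spuriously positive importance. Shapley-value attribution is out of
  scope; permutation importance is the native ranking.
- **Subgroup audit**: per-stratum metrics on pooled out-of-fold
  predictions; demographic stratifications are mutually exclusive per
  family (age group, sex, sex × age, race/ethnicity) while diagnostic
  strata may overlap; strata with a single class are flagged undefined
  and excluded from the gap (max − min AUROC) and the ≥0.90 / ≥0.95 bar
  counts. Pairwise feature-set p-values are reported unadjusted with
  .05/.01/.001 star thresholds; no multiplicity correction is applied.

## Problem sizes and numerical choices

Default analysis and acceptance runs use 2000-encounter cohorts (≈1620
evaluated after the development carve-out) and, for multi-seed claims,
five seeds; these sizes give stable orderings while keeping single-CPU
runs in the minutes range. The acceptance grid is trimmed to 60 trees ×
two depths. A single global seed fans out to per-stage seeds via
`numpy.random.SeedSequence` spawning, so stages are independently
reproducible; all derived seeds stay below 2³¹. Zero-sentence encounters
score 0 (kNN) or −3 (Likert) with explicit flags. Probability exactly at
the 0.5 threshold classifies positive.

## Known limitations

- The generator's template language is far simpler than clinical prose;
  hashed embeddings separate it more cleanly than any encoder separates
  real notes, so absolute AUROCs here run higher than real-data values.
  Relative orderings and gap structure, not levels, are the claims under
  test.
- The Likert stand-in scorer is deterministic and lexicon-driven; it
  cannot exhibit hallucination, prompt sensitivity, or parse failures
  except those synthetically injected through the parsing contract.
- Calibration of predicted probabilities is out of scope (only
  discriminative comparison is implemented), as is any real-EHR
  extraction, de-identification, or geocoding.
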