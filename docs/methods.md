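# Methods

This note documents the models, defaults and design choices behind
`crisnss`, and what the synthetic test bed does and does not demonstrate.

## Extraction model

The unit of classification is the **mention**: one cue-phrase occurrence
inside one sentence. Sentences are split on sentence-final punctuation
followed by whitespace with a short abbreviation guard list; tokens are
lowercased alphanumeric runs (apostrophes kept), with no stemming and no
stop-word removal — negation words are features, removing them would be
self-defeating.

The hybrid decision is strictly layered:

1. **Negation rule.** A negation cue (`no, not, denies, denied, without,
   nil, never, absence` by default) within the 5 tokens immediately
   preceding the cue, in the same sentence, forces `not_positive`. The
   5-token pre-cue window is the common clinical-NLP convention; widening it
   trades precision for recall on long coordinated sentences.
2. **Experiencer rule.** A family-member cue anywhere in the sentence forces
   `not_positive`, because attributions like "his mother describes social
   withdrawal" concern a relative. Sentence-wide scope is deliberate:
   attributions often sit far from the cue.
3. **Linear model.** Everything else goes to a per-symptom linear classifier
   over binary unigram + bigram indicators of the sentence. Ten independent
   models are the default (one per symptom); a single shared model with the
   symptom label as a categorical feature is available
   (`cross_validate(per_symptom=False)`).

A decision value of exactly 0 maps to `not_positive`: when the model has no
evidence, the scale should not gain a symptom — this favours precision,
which is the operating regime the extraction approach is designed for.

**Trainer.** The objective is ½‖w‖² + C·Σ hinge with C = 1.0 by default
(exposed per run). The optimiser is cyclic dual coordinate descent with the
intercept as a regularised constant feature; examples are sorted by a stable
key first, so training is order-independent and bit-reproducible. The
duality gap is driven below 10⁻¹² of the objective, which certifies
‖w − w*‖ ≤ √(2·gap); tests verify agreement with two independent
optimisers (an SLSQP solve of the equivalent slack-variable QP, and a
long-run projected subgradient descent) to 10⁻⁶. Rule-forced mentions are
**excluded from training**: the rules pre-empt them at inference, so
training on them would double-count deterministic evidence.

Cue inventories are configuration, not canon. The default lexicon
(`crisnss/lexicon.py`) contains 2–4 surface phrases per symptom; real
deployments should extend it from their own corpus. Unseen tokens at
prediction time contribute nothing (bias-only decision in the limit).

## Composite scale

The ten binary flags are summed with equal weights to a 0–10 score and
dichotomised at ≥2 (a parameter; 2 is the default a-priori choice).
Cronbach's α uses sample (n−1) variances, the standard psychometric
convention; it is computed on whatever extraction window produced the
flags. Scale construction is intentionally plain — no IRT, no subdomain
factors — because the package's claim is about feasibility of text-derived
measurement, not psychometric structure.

## Evaluation

Cross-validation is stratified (per symptom, per gold label) with
scikit-learn's `StratifiedKFold`, seeded. Confusion counts are **pooled over
folds before metrics** (micro-average): per-fold precision for a symptom
with 10 positive instances is too unstable to average meaningfully; per-fold
macro means are reported as secondary columns. Metrics with a zero
denominator are NaN, never 0 or 1. When the rules absorb one class entirely
in a training fold (as happens on fully rule-decidable corpora), the fold's
model degenerates to a bias-only constant — the hybrid is then exactly the
rule set, which is the intended behaviour. Inter-annotator agreement uses
percent agreement and Cohen's κ with chance agreement from each annotator's
own marginals.

## Epidemiological layer

- **Count reconstruction** from printed group sizes and 1-dp percent
  prevalences rounds half-up; a reconstructed count can differ from the true
  one by ±1 (e.g. 41.0% of 7678 gives 3148 where the true count is 3149),
  which propagates to roughly ±0.005 on reconstructed odds ratios and can
  move a CI bound by one unit in the second decimal.
- **2×2 odds ratios** use the Woolf/Wald CI with z = 1.96 and a Wald p.
  Zero cells raise an error by default; a 0.5 continuity correction is
  opt-in, never silent. Exact-conditional intervals are out of scope.
- **Regressions** delegate to statsmodels: `Logit` (Newton, gradient
  tolerance 10⁻⁸, with a quasi-Newton fallback when quasi-separation of a
  sparse category makes the Hessian singular — the affected terms are
  flagged, the regular terms are unaffected), `OrderedModel` for the
  proportional-odds model (cutpoints strictly increasing by
  parameterisation), and `OLS` for length of stay. Coefficients beyond ±15
  log-odds are flagged as probable separation. Wald CIs and p values
  throughout.
- **Adjustment ladder**: unadjusted → model 1 (age bands + sex) → model 2
  (+ marital status + employment) → model 3 (+ delusions/hallucinations +
  depression); the designs are nested by construction. References are the
  most prevalent level (male, single, unemployed, construct absent) except
  age, where 20–29 — the youngest band of sufficient size — is the
  reference. Missing covariate values become explicit `_missing` indicator
  levels rather than being imputed or dropped; an optional age<40 indicator
  and its product with the exposure support effect-modification analyses.
- **Outcomes** derive from admission intervals: admission = any admission
  starting in the follow-up window; readmission = a new admission within
  365 days (inclusive — "12 months" needs a day convention) of an in-window
  discharge; length of stay = days of the first in-window admission.
  Overlapping intervals are merged with a warning. When several covariate
  observations exist, the one nearest the index date is used, ties broken
  toward the earlier record.
- The ordinal model accepts the 0–10 score as either outcome or exposure;
  the direction must be chosen explicitly in the `DesignSpec` rather than
  defaulted, since both are scientifically meaningful.

## Synthetic cohort generator

The generator's defaults are the study conditions of a large urban
secondary-mental-healthcare cohort (n = 7678 adults with schizophrenia):

- **Demographics** are drawn independently from that cohort's marginal
  distributions, including realistic missingness (marital ~1.5%, employment
  ~27%, HoNOS constructs ~9%). Independence between factors is a documented
  simplification — sufficient for recovery testing, unrealistic as
  epidemiology.
- **Symptom flags** follow a latent-severity model: flagᵢ ~
  Bernoulli(logit⁻¹(aᵢ + λz + demographic shifts)) with z ~ N(0,1) shared
  across the ten items. Intercepts aᵢ are solved by quadrature so marginal
  prevalences match the reference values (30.5% down to 5.7%). The loading
  λ = 1.7 is the compromise between the reference scale reliability
  (α ≈ 0.78 needs λ ≈ 1.8) and the reference ≥2-symptom prevalence
  (41% needs λ ≈ 1.6); at 1.7 the generated cohort shows α ≈ 0.76 and
  prevalence ≈ 39–40%. Demographic shifts (female −0.35 log-odds; age-band
  shifts declining from the 20s) are applied centred so calibration is
  preserved.
- **Notes** are templated English: each patient gets 1 + Poisson(3)
  correspondence documents dated 2008–2010; every true symptom is affirmed
  per note with probability 0.9, false symptoms attract negated (0.15) and
  family-attributed (0.05) mentions, any symptom can appear as a topical
  mention (0.05, e.g. "the psychoeducation group discussed apathy"), plus
  symptom-free filler sentences. Gold standoff annotations index the
  planted cue exactly. Affirmed/negated/family wordings are decidable by the
  rule grammar; topical mentions are the part that requires the learned
  model — a corpus restricted to the former ("perfect grammar") is the
  regime where the hybrid is provably exact, and the labelled-instance
  corpus with 10% positive-label noise is the benchmark for learner
  behaviour under annotation noise. Linguistic variety is explicitly not a
  goal: passing extraction tests shows the pipeline is correct, not that the
  lexicon would cover real clinical prose.
- **Outcomes** are generated from the same model-3 design that is later
  refit: admission ~ Bernoulli(logit⁻¹(α + ln(1.24)·exposure + covariate
  terms)) with baseline ≈ 18%; readmission likewise with OR 1.58 and
  baseline ≈ 25%; length of stay = 60 + 20.5·exposure + covariate terms +
  N(0, 30) days, floored at 1 day. The 60-day intercept keeps the floor
  essentially inactive (<2.5% of mass below 1 day for the unexposed), so
  OLS stays unbiased; a log-normal noise option exists for skewed-LOS
  experiments. Planted effect sizes default to the reference study's
  fully-adjusted estimates so the recovery study targets published values.

## Problem sizes and numerics

The recovery study refits model-3 designs on fresh cohorts of n = 7678
(admission), 1612 (readmission) and 1609 (length of stay) over 200 seeded
replicates; nominal 95% Wald intervals are expected to cover the generating
value in 93–97% of replicates (binomial noise ≈ ±3% at 200). Extraction
benchmarks use 100 instances per symptom (perfect grammar) and 2000 per
symptom (noisy corpus). All randomness flows from
`numpy.random.SeedSequence` children of a single seed; derived seeds stay
below 2³¹.

## Known limitations

- The cue lexicon, negation and experiencer inventories are small defaults,
  not validated clinical resources.
- Temporality is document-date only; no within-text tense or history
  handling beyond the negation window.
- The generator's demographic independence and Gaussian LOS noise are
  simplifications; results on synthetic data quantify pipeline correctness
  and estimator calibration, not real-world extraction accuracy.
- Odds-ratio reconstruction from printed marginals inherits ±1-count
  rounding error; agreement beyond ±0.01 on the OR scale is not attainable
  from 1-dp prevalences.
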