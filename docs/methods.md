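# Methods

## The assessment model

The pipeline estimates a rating-scale total from language features by
penalized linear regression. Writing X for the N×D matrix of pooled
response embeddings and y for the scale totals, each outer
cross-validation fold fits

  min over (β, b) of ‖y − Xβ − b‖² + λ‖β‖²,

with the intercept b unpenalized and the features z-scored within the
training fold (the penalty grid spans 32 orders of magnitude, which only
makes sense on a common feature scale). The solve uses the SVD of the
centred design, so one decomposition yields the coefficients for the whole
grid; coefficients therefore shrink monotonically in λ by construction,
and the fit equals the normal-equations solution to numerical precision
(tested to 1e-8).

Accuracy is the Pearson correlation between y and the pooled out-of-fold
predictions ŷ — one figure per model, not a per-fold average — with its
two-sided p from the t transform on N−2 degrees of freedom.

## Cross-validation and stratification

Ten outer folds are stratified on 4 quantile bins of y. Bins are rank
blocks with stable tie-breaking, so integer scale totals (range 5–35 for
five 1–7 items) are handled deterministically. Within bins, members are
dealt to folds by rank against the running fold totals and then refined by
within-bin swaps until the fold totals of y are as equal as the integer
grid allows.

Balancing fold *totals*, not just counts, is load-bearing: the accuracy of
pooled out-of-fold predictions contains an artifact equal to minus the
between-fold share of outcome variance. A fold-constant predictor (the
infinite-penalty limit) correlates with y at exactly −√(SS_between/SS_total)
no matter how small the fold-mean differences are, because the ratio is
scale-free. With count-only stratification this artifact is about −0.07;
with total-balanced folds it is below 0.005 in magnitude.

## Penalty selection

Inside each outer training set, a single stratified 75/25
analysis/assessment split scores every λ in the grid by assessment mean
squared error. The default rule (`min_rmse_1se`) returns the **largest** λ
whose MSE lies within one standard error of the minimum; `min_rmse`
returns the plain minimiser. The one-SE guard matters because comparing 33
penalties on one noisy holdout suffers a winner's curse: with pure-noise
features the plain minimiser picks a spuriously "validated" low penalty in
roughly half the folds, which skews the null distribution of accuracy left
(mean −0.02, twice the nominal rejection rate in our simulations). Under
the one-SE rule the null accuracy is centred (mean −0.005) and its test is
slightly conservative (≈1.5–2% rejections at nominal 5%), the preferable
failure mode for an assessment method. After selection the model is refit
on the entire outer training set at the chosen λ. The selection split is
single-shot per fold and seed-controlled.

Because the inner criterion is MSE, selection is defined even when the
assessment outcomes happen to be constant; no separate error path exists
for that case.

## Model comparison

*Same outcome.* Per-participant errors y − ŷ are reduced to magnitudes
(|e| by default; raw and squared are available) and compared with a paired
t-test. Raw cross-validated errors have near-zero mean for any reasonable
model, so only magnitude comparisons discriminate accuracy. Two identical
models give t = 0, p = 1 by definition.

*Different outcomes.* Participants are resampled with replacement jointly
for both models; each replicate yields one accuracy per model, and
p = min(1, 2·min(P(Δr ≤ 0), P(Δr ≥ 0))) over the paired replicate
differences, ties at zero split between the sides (so identical models
give p = 1). Default 1000 replicates, seed required. The test is exact in
its conditioning: it treats the two fitted prediction vectors as data.
Simulations that *refit* both models on every simulated dataset therefore
overstate its size whenever the two models carry independent fitting
noise; in the method's actual use case — one response feature set
predicting two outcomes, as in the discriminant-validity comparisons —
the measured type-I rate is ≈8% at α = 5%, N = 608. This residual
anticonservatism is a property of bootstrap inference conditional on
fitted models and is documented rather than patched.

## Reliability and ceilings

For a k-item scale: inter-item mean r (mean of the k(k−1)/2 pairwise
Pearson correlations), corrected item-total mean r (mean correlation of
each item with the sum of the others), and Cronbach's
α = k/(k−1)·(1 − Σvar(itemⱼ)/var(total)). Test–retest coefficients cannot
be estimated from one administration and are accepted as user-supplied
constants. Two ceiling conventions are exposed: `paper` judges an observed
accuracy directly against a reliability value; `classical` uses the
attenuation bound √(rel_outcome·rel_predictor). On parallel items, α
matches the Spearman–Brown form k·r̄/(1+(k−1)·r̄), which the tests verify by
simulation.

## Information content

The Diversity Index is 2^H with H the Shannon entropy in bits of the
pooled token relative frequencies. Entropy is computed in base 2 (forced
by the 2^H definition), and tokens are normalized with the same
lowercase/punctuation-stripping rule used by the decontextualized
embedder, so the index describes exactly the words the models saw. DI lies
in [1, number of distinct types], reaching the upper bound only for a
uniform distribution. Correlation magnitudes are banded for reporting:
0.20–0.39 weak, 0.40–0.59 moderate, 0.60–0.79 strong, 0.80–1.0 very
strong; below 0.20 we label "negligible" rather than erroring.

## The synthetic-data generator

The generator is a minimal statistical world reproducing every quantity
the pipeline computes:

- **Latent traits.** Two standard-normal vectors with population
  correlation ρ (default 0.85, the level at which the two well-being
  scales empirically correlate).
- **Scale items.** Parallel indicators: item = a·trait + √(1−a²)·noise,
  affinely mapped onto the 1–7 grid (midpoint at trait 0, six SDs across
  the range) and rounded. Population inter-item r = a² before rounding;
  defaults calibrate a to inter-item targets 0.76 (HILS) and 0.73 (SWLS).
  Rounding to seven points attenuates observed reliability by a few
  hundredths (e.g. 0.76 → ≈0.70 at N = 608); this is documented, not
  compensated, and reliability assertions in tests therefore use the
  pre-rounding items. Helpers invert the Spearman–Brown relation to set a
  from a target total reliability.
- **Embeddings.** Column j is √s·wⱼ·trait + √(1−s)·noise with fixed random
  weights wⱼ, rescaled to unit population variance. The population
  multiple correlation with the trait is √(A/(1+A)), A = Σ s·wⱼ²/(1−s) —
  the closed-form oracle in the tests. The default is D = 64 columns at
  s = 0.05: a small per-column signal spread over many correlated columns,
  as in real embedding features, giving a population multiple-R ≈ 0.88 and
  hence cross-validated accuracies on the scale observed for such
  assessments (~0.8–0.9 against a ceiling of √reliability).
- **Token streams.** Tokens are drawn from construct-specific
  vocabularies (12 positive, 12 negative, 12 neutral words) with a
  logistic weight shift: weight ∝ base·σ(tilt·valence·trait), monotone and
  bounded in the trait. Word responses have exactly 10 tokens; text
  responses are longer streams (default 70 tokens) from the same tilt.
  A separate generator emits *order-coded* streams — fixed pairs whose
  orientation, not frequency, tracks the trait — so the
  contextual/decontextual contrast can be tested: unigram-based features
  are constant in the pair tokens by construction while order-sensitive
  features carry the signal.

All components draw from named substreams of one integer seed, so a
configuration reproduces bit-identically and item noise, embedding noise
and token draws are conditionally independent given the traits.

What the generator does **not** emulate: real English prose (token streams
are statistical stand-ins), response-length variation (lengths are fixed
per format, where real word-responses average ≈9.8 words with SD ≈1),
response styles such as acquiescence, and the vocabulary scale of real
corpora (36 types per construct versus hundreds in real responses, so
diversity indices are on the order of 36, not hundreds). Passing tests
demonstrate the statistical machinery — calibration, ceilings, ordering
of reliabilities, context sensitivity — not performance on natural
language.

## Toy embedders

`HashEmbedder` assigns each (token, layer) a fixed standard-normal vector
derived from a hash of the token string; with `context_strength > 0` a
second vector keyed on (previous token, token) is added. Sequences are
wrapped in boundary markers which pooling excludes by default (a flag
includes them). The first real token's left neighbour is the start marker
in both extraction modes, so single-token responses embed identically
contextually and decontextually — a contract the tests rely on. For real
transformer backends, sub-token vectors of one word should be mean-pooled
to a word vector before response pooling; this adapter path is documented
but not exercised by the test-suite.

## Problem sizes

Simulation-based checks use the sizes at which their statistical targets
are sharp while remaining quick: reliability closed forms at n = 5000,
null calibration and comparison calibration at 200 simulated datasets
(N = 300 and N = 608 respectively), ceiling recovery averaged over 10
seeds at N = 608, and the context contrast at N = 400. The full test-suite
runs in about half a minute on one CPU; the acceptance script in a few
seconds.

## Known limitations

- The pooled out-of-fold correlation is not exactly pivotal: its null
  distribution depends on how aggressively the selected penalties shrink,
  so the t-based p-value is conservative under heavy shrinkage (see
  Penalty selection) and the bootstrap comparison is mildly
  anticonservative when compared models carry independent fit noise.
- Stratified, total-balanced folds make fold assignments depend on y;
  this is standard for stratified regression CV and involves no leakage
  (each fold's model never sees its own labels), but for tie-free
  continuous outcomes the dealing is rank-determined and different seeds
  can coincide.
- Rounded 1–7 items attenuate reliability relative to the pre-rounding
  calibration targets; calibration statements refer to the continuous
  items.
- Real transformer backends are adapters by contract only; nothing in the
  package downloads or bundles a language model.
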