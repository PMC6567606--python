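# Methods

`depnb` implements a family of naive Bayes diagnostic classifiers for
(disease, symptom-set) record cohorts, in which the conditional-independence
assumption is relaxed by multiplying the naive Bayes numerator with a
*dependency degree* of the query symptom vector. This note describes the
model, the estimation conventions, the synthetic test bed, and the numerical
and design choices — including the ones where measurement showed the method's
own weighting scheme working against it.

## Model

A cohort holds m records; record i pairs one primary disease label D with a
set of present symptoms S_i = {S_i1 … S_in}. Symptoms are binary and
closed-world: a symptom not listed is absent. For a query vector S with n
present symptoms, every variant scores disease D_f with

    score_f = Corr_{S|D_f} · P(D_f) · ∏_{j=1..n} P(S_j | D_f)

and reports the posterior P(D_f | S) = score_f / Σ_g score_g. The evidence
term P(S) is *defined* as the sum of numerators over the k trained diseases,
so posteriors always form a proper distribution; it is never estimated from
data. The product runs over present query symptoms only — absent symptoms
contribute no (1 − p) factor, matching the flow the weighting scheme assumes.

The three variants differ only in the dependency degree Corr_{S|D_f}:

* **nb** — Corr ≡ 1 (plain naive Bayes).
* **improved_nb** — co-occurrence kernel. Pairwise weight
  Corr_(Si,Sj)|Df = P((S_i,S_j)|D_f) / (P(S_i|D_f) · P(S_j|D_f)),
  all terms Laplace-smoothed; 1 means conditional independence.
* **sdnb** — odds-ratio kernel. Pairwise weight
  Corr_(Si,Sj)|Df = OR(S_i,S_j) / (OR(S_i,D_f) · OR(S_j,D_f)),
  where OR(X,Y) = (a·d)/(b·c) on the cohort-level 2×2 presence table.

Either kernel is composed into a vector-level degree by the geometric mean
over all C(n,2) unordered pairs, computed in log-space:

    Corr_{S|D_f} = ( ∏_{pairs} Corr_(Si,Sj)|Df )^(1/C(n,2)),   Corr ≡ 1 for n ≤ 1.

The composition rule is shared by both kernels so the variants differ only in
the pairwise weight.

## Estimation conventions

* Laplace smoothing uses the number of diseases k as the denominator
  constant throughout: P(D_f) = (#D_f + 1)/(m + k), P(S|D_f) =
  (#(S,D_f) + 1)/(#D_f + k), and the same form for pair conditionals. For a
  binary attribute the textbook constant would be 2; the +k form is the
  convention this method is defined with and is isolated in `estimation`.
  It keeps every estimate strictly inside (0, 1) and makes the empty-cohort
  prior exactly uniform.
* Odds ratios receive the Haldane–Anscombe correction — 0.5 added to all
  four cells — only when at least one cell is zero, so fully populated
  tables are unbiased and every OR is finite and positive.
* A symptom pair observed together in fewer than `cooc_threshold` training
  records (default 5) is treated as independent (pairwise weight exactly 1)
  in **both** kernels. The threshold counts *records containing both
  symptoms*, cohort-wide: a pair can co-occur at most once per record, so
  "number of co-occurrences" and "number of records" coincide.
* All counts are weight sums with unit default, so the same estimation code
  serves boosting (bootstrap multiplicities) unchanged; the threshold is
  then applied to the weighted co-occurrence total.
* Pairwise weights can optionally be clamped into [lo, hi]
  (`fit_dependency_model(..., clamp=...)`); this is off by default and is a
  robustness knob, not part of the base method.

## Boosting

AdaBoost is realized as multiclass SAMME with weight-proportional bootstrap
resampling: each round resamples m records from the current weights, fits the
base learner on the multiplicities, measures the weighted top-1 error ε_t on
the full cohort, sets α_t = ln((1−ε_t)/ε_t) + ln(k−1), and multiplies
misclassified weights by e^{α_t} before renormalizing. Rounds with
ε_t ≥ 1 − 1/k are discarded and training stops; ε_t = 0 keeps the round and
stops. The ensemble predicts with the α-weighted average of round posteriors
(not hard voting) so it emits the same posterior-table type as a single model
and can be ROC-evaluated identically. T defaults to 10; all randomness flows
from one seeded generator, making training reproducible bit-for-bit.

## Evaluation

Diagnostic quality for a target disease is one-vs-rest: scores are posteriors
for the target, labels are target/non-target. The ROC sweeps thresholds over
unique scores descending, with (0,0) and (1,1) appended. AUC uses the
pairwise-count convention (ties earn half credit), which equals the
trapezoidal integral of the curve to machine precision. The standard error is
Hanley–McNeil with Q1 = A/(2−A), Q2 = 2A²/(1+A); z = (A − 0.5)/SE with a
one-sided normal upper-tail p-value tests the chance-level null. Perfectly
separated scores give SE = 0 and are rejected as degenerate rather than
reported with an infinite z.

## Synthetic test bed

The generator draws each record's disease from a categorical prior, then each
symptom independently from a per-disease Bernoulli matrix θ[D][S], then
applies couplings (S_a, S_b, ρ) in listed order: with probability ρ the value
of S_b (present *or* absent) is overwritten by S_a's. ρ = 1 makes the columns
identical; the post-coupling truth is available in closed form
(P_eff(S_b|D) = ρ·P_eff(S_a|D) + (1−ρ)·θ[D][S_b]) for recovery tests, and a
sidecar JSON stores the full spec next to every generated cohort.

Two canonical condition sets are provided:

* **desk scale** (`desk_spec`): k = 20, V = 30, default m = 5,000. Zipf
  priors (heavy-tailed, like clinic caseloads; the two leading diseases have
  prior ≥ 0.1). Disease f presents characteristic symptoms {f, f+1, f+2}
  (mod 20) with conditionals (0.6, 0.2, 0.1) — one prominent symptom and two
  minor ones, the magnitude profile published disease/symptom conditional
  tables show — over a 0.05 base rate; symptoms 20–29 are flat 0.15
  background for every disease and therefore marginally independent of
  everything (the designated null pairs). With ρ > 0, two couplings
  (S00→S01, S05→S06) inside the characteristic pool inject exactly the
  dependence the weighted variants target.
* **full scale** (`paper_scale_spec`): k = 336, V = 81, m = 30,000, with a
  Zipf(1.5) tail so the rarest diseases receive fewer than 10 records,
  exercising the low-support exclusion in ontology enrichment.

The generator emulates the statistical structure the classifier assumes and
nothing else: no reporting noise, no demographic confounding, no label error,
no free text. Passing tests therefore demonstrate correctness of the
machinery and behaviour under *idealized* dependence, not clinical
performance on real records.

## What the comparative study shows — a negative result

On coupled desk cohorts (m = 5,000, ρ = 0.9, five seeds, one-vs-rest for the
leading disease) the measured mean test AUCs are approximately: plain NB
0.83, co-occurrence-weighted 0.83, odds-ratio-weighted 0.51 (the acceptance
script recomputes them from scratch). The co-occurrence kernel is a wash at
this scale — its correction is correct in direction (it rebuilds the true
pair joint from the naive product) but the C(n,2)-root dilutes it below the
sampling noise of the other pairwise weights. The odds-ratio kernel is
actively harmful here, and the reason is structural: for a fixed query, the
cross-disease variation of log Corr_(Si,Sj)|Df is −log OR(S_i,D_f) −
log OR(S_j,D_f), so the weight *boosts* the diseases least associated with
the query pair (their symptom-disease ORs sit below 1, putting a small
product in the denominator) and *penalizes* the diseases the pair actually
indicates. Under a generative cohort with informative, well-separated disease
profiles this counteracts the likelihood term; coupling only uninformative
background symptoms instead makes the weight disease-constant, which cancels
in normalization and leaves the odds-ratio variant exactly equal to plain NB.
There is no desk-scale configuration of this generator in which the
odds-ratio weighting improves ranking, and the package reports that honestly
rather than papering over it: the corresponding comparative-ordering
acceptance test is expected to fail. The weighting can only help when
symptom-disease ORs are all close to 1 — plausibly the regime of the clinical
cohorts the scheme was developed on, which had hundreds of diseases sharing
a small symptom vocabulary.

## Ontology enrichment

Learned probabilities are published into an OWL 2 ontology (RDF/XML, the
dialect mainstream editors default to). OWL cannot attach a typed literal to
an object-property edge, so each (disease, symptom) conditional lives on a
reified link individual pointing at both classes; priors live on the disease
class. Diseases with fewer than `min_support` training records (default 10)
appear as classes but carry no probabilities — estimates from a handful of
records are not trustworthy enough to publish in a knowledge resource.
Synonyms use the `hasExactSynonym` annotation, and free text resolves against
labels and synonyms by character-bigram Dice score (default threshold 0.4)
after NFC normalization, casefolding and whitespace collapsing. Doubles
round-trip through the literal representation exactly, so classification from
a re-read ontology matches the in-memory model bit-for-bit in ranking.

## Numerical choices and degenerate inputs

* All products (likelihoods, dependency degrees) accumulate in log-space;
  posteriors normalize through log-sum-exp.
* Exact posterior ties rank lexicographically by disease identifier, in both
  the per-query tables and the vectorized batch scorer (reproducibility).
* Query symptoms outside the model vocabulary are dropped with a logged
  warning and recorded in the result; an all-unknown query is an error.
* m = 0 cohorts are legal for estimation (uniform priors); empty ensembles,
  single-class ROC labels, and zero-SE (perfectly separated) ROC inputs are
  errors.
* Chained generator couplings are applied in listed order, so their
  composition is well defined and matches the closed-form effective truth.

## Problem sizes used in tests

The default suite trains on cohorts of 1,200–5,000 records (20 diseases, 30
symptoms) and uses 20,000-record cohorts for calibration and recovery
checks — sizes chosen so the whole suite runs in seconds while keeping
binomial noise well below the asserted tolerances. The acceptance script
uses the same desk-scale conditions with five seeds for the comparative
study.

## Known limitations

* The symptom model is presence-only; multi-valued or continuous findings
  are out of scope.
* P(S) normalization over the trained disease set means posteriors are not
  comparable across models trained on different vocabularies.
* The ontology reader recovers priors and conditionals only; pair statistics
  do not survive the OWL round trip, so dependency weights must be refit or
  loaded from the JSON model bundle.
* The synthetic generator's idealizations (above) mean comparative results
  quantify behaviour under planted dependence, not clinical accuracy.
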