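# Methods

## Problem and model

The predictor classifies fixed 41-bp DNA windows as 6mA-positive or
negative, with the candidate adenine at the central position (21), and then
applies the classifier to promoter regions by tiling them into consecutive
non-overlapping 41-bp windows.  All promoter coordinates are 1-based and
inclusive, so window *w* spans bases `(w-1)·41+1 … w·41`; BED output
converts to 0-based half-open.  This tiling is the only convention
consistent with whole-window site ranges such as 165–205, 1026–1066 and
1313–1353 (windows 5, 26 and 33 of a 1.5-kb promoter), and the package
asserts that reconstruction in its tests.

## Encodings

Five feature groups, concatenated in a fixed order (DNF 16, NCP 123,
AMIP 40, GC 1, MBED 164 = 344 columns).  Conventions that were open and are
fixed here:

* **AMIP lag range** is k = 1…40, every lag realizable in a 41-mer.  The
  profile must be a vector over lags for multi-feature selection from this
  group to be meaningful.
* **AMIP marginals** are the row/column sums of the lag-k joint itself (not
  whole-window base frequencies).  This guarantees `MI_k ≥ 0`, with exact
  zero whenever the joint factorizes (e.g. homopolymers).  Empty cells use
  the `0·log 0 = 0` convention; no pseudocounts.  Logs are base 2 (bits);
  any fixed base merely rescales the features.
* **GC transform** is `log(1 + GC fraction)` (natural log): defined at
  GC = 0, strictly monotone, bounded by log 2.
* **NCP and MBED are positional** (3 and 4 values per position).  A
  selected-feature census containing eight NCP and nine MBED features is
  only possible if those groups are multi-dimensional, so aggregated
  variants were rejected.  The total dimension is therefore 344; a
  published description quoting "124 dimensions" for this feature family
  is not reproducible under any natural sizing of the five groups and was
  set aside in favour of the self-consistent convention above.
* MBED uses the non-alphabetical bit order A, G, C, T exactly as published;
  the encoding is invertible and the tests check
  `decode ∘ encode = identity`.

## Feature selection

The hybrid selector intersects the top-40 of two rankings:

* **Random forest arm:** mean impurity-decrease importance from a 500-tree
  forest (the same forest size as the ensemble's base model); ties,
  including the zero-importance tail, break by feature name so the ranking
  is deterministic.
* **Stepwise arm:** forward stepwise logistic regression scored by AIC.
  The published description says only "stepwise regression"; forward
  selection with AIC entry order was chosen because a backward start from
  344 features is not feasible and entry order gives a natural ranking.
  For speed, candidates at each step are screened by the Rao score
  statistic (vectorized over all remaining columns, equivalent to one
  Newton step of likelihood gain); the top-scoring few are refit exactly
  with `statsmodels.Logit` and admission is decided by AIC.  Perfect
  separation — routine on strongly separable data — switches that fit to
  an L2-penalized logistic regression whose penalized log-likelihood feeds
  the AIC, so the walk never aborts.  When the walk stops before 40
  entries, remaining rank slots are filled by single-feature (marginal)
  AIC so the top-40 prefix is always defined.

An empty intersection of the two arms falls back to the union of the two
top-20 prefixes, with a warning; realistic runs never hit this branch.

## Ensemble

Base models and fixed hyperparameters: RBF-kernel SVM (C-classification,
C = 1, γ = 1/n_features — both library-conventional since unstated), random
forest with 500 trees and 5 candidate variables per split ("five splits"
read as the per-node feature sample, the vocabulary of the reference R
implementation), and stochastic gradient boosting with 150 trees,
interaction depth 3, shrinkage 0.1 and subsample fraction 0.5 (the
"stochastic" default of the reference implementation).  Features are
standardized (train-set mean/sd) for the SVM only — trees are
scale-invariant; whether the original server standardizes is unstated, so
the choice is recorded in the model metadata (`svm_standardized`).

The ensemble score is the mean of the three binary votes, quantized to
{0, ⅓, ⅔, 1}; the call is positive at score ≥ ⅔ (at least two favourable
votes).  M = 3 is odd, so ties are impossible and the call equals a
brute-force majority over the vote triple (asserted over all 8 cases).

The dual-species intersection calls a window positive only if both models
do; the combined score is `min(score_a, score_b)` — the published rule
defines only the binary intersection, and min is the conservative
convention consistent with it.

## Metrics

Sensitivity, specificity, accuracy and MCC are computed from the confusion
matrix with the standard formulas (integer numerators, so the analytic
cases ±1 and 0 are exact).  A zero marginal leaves the affected ratio NaN
with a flag; MCC with a zero denominator is reported as 0 and flagged (a
common convention; the source formulas do not address it).  AUC is the
trapezoid over the unique-threshold ROC, equal to the Mann–Whitney
statistic with ties counted ½ — well-defined for the 4-level vote scores —
and is cross-checked in tests against an O(n²) pairwise oracle.  TOPSIS
uses vector (L2) normalization, equal weights by default (no weighting
scheme is published) with all evaluation metrics treated as benefit
criteria, Euclidean distances to the ideal/anti-ideal points and closeness
`C = d⁻/(d⁺+d⁻)`; the engine is validated against an independent
textbook-steps oracle since the decision matrix behind the published tool
ranking is not available.

## Synthetic data

The generator emulates the structure of real 6mA benchmarks — balanced
sets of adenine-centred 41-bp windows — with a tunable, fully known signal
instead of methylation biology: positives carry a short motif (default
`GAGG`) immediately downstream of the central A with probability
`separation`; negatives never do (chance occurrences in the motif slot are
scrubbed so `separation` is the exact signal rate).  Backgrounds are i.i.d.
uniform by default.  **Both classes are adenine-centred**: negatives model
unmethylated adenine sites, as in real benchmarks, and this makes the two
classes exchangeable at separation 0 (with positives-only centring,
position-21 identity alone would allow ~0.87 accuracy in a "no-signal"
benchmark, which would make the null experiments meaningless).

Promoter simulation rewrites `sites_per_promoter` window-aligned slots of
an i.i.d. background sequence as positive-style windows and records their
coordinates in an exact truth table (all other aligned slots are scrubbed
of positive look-alikes).

What passing these tests shows: the pipeline recovers a planted, window-
aligned, position-anchored signal and is honest under label shuffling.
What it does not show: performance on real genomes, whose 6mA signal is
weaker, context-dependent and not window-aligned, and whose base
composition is neither uniform nor i.i.d.

## Study sizes and numerical choices

The recovery experiments run at desk scale, chosen once: 2000+2000
training and 500+500 test windows for the headline recovery and the
ten-seed label-shuffled null; selection recovery at n = 2000 over 344
columns with ten planted features; promoter scans with two 400+400-window
models over 15 promoters × 3 planted sites (five seeds in the test suite).
Smaller auxiliary property checks (e.g. ensemble-never-worse-than-its-
worst-member) use 200+200 windows.  The null experiment shuffles the
labels of *both* the training and the test split — the correct permutation
null; testing shuffled-trained models against structured labels would
measure chance correlations with the real signal instead.

Window validation is strict (exactly 41 nt, A/C/G/T only, unique
accessions); reading FASTA normalises IUPAC ambiguity codes to N and
rejects U and non-IUPAC characters with their position.  Promoter tiling
discards a trailing remainder < 41 bp rather than padding, and by default
drops N-containing windows while preserving the coordinates of the
survivors; an `excise` mode instead deletes N characters before tiling for
byte-compatibility with trim-then-split pre-processing, at the cost of
coordinate fidelity.

## Limitations

* Trained models are only as transferable as their training windows; the
  synthetic models here are demonstrations of the machinery, not reusable
  predictors for real genomes.
* The per-gene methylation rate is defined as total predicted windows ÷
  scanned promoters of the species (zero-site promoters count in the
  denominator).  Published per-species rates of this kind are not always
  consistent with their own site/gene tallies, so the definition is fixed
  here explicitly.
* No probability calibration: the ensemble score takes only four values.
* Strand handling is the caller's responsibility; input promoters are
  assumed already oriented 5'→3'.
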