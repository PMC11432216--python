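# Methods

`adpep` classifies antidiabetic peptides by the diabetes type they target:
label 0 marks peptides effective against type 1 diabetes mellitus (T1DM),
label 1 peptides targeting type 2 (T2DM).  The pipeline has five stages —
featurization, descriptive statistics and hypothesis tests, lasso feature
selection, classification, and cross-validated evaluation — plus a seeded
synthetic-data generator that stands in for the curated peptide database
such analyses are normally run on.

## Feature extraction

Each peptide sequence maps to 737 numeric descriptors in a fixed,
documented column order:

| block | columns | definition |
|---|---|---|
| AminoCount_A…Z | 26 | occurrences of each letter |
| AvgPosition_A…Z | 26 | mean 1-based position of each letter; 0 encodes absence (real positions are ≥ 1, so the sentinel is unambiguous) |
| PairCount_AA…ZZ | 676 | overlapping dipeptide counts |
| Entropy | 1 | Shannon entropy of the residue composition, bits; 0·log 0 ≡ 0 |
| MaxRepeat | 1 | longest single-residue run |
| LZComplexity | 1 | phrase count of the Lempel–Ziv (LZ76) exhaustive-history parsing |
| PeptideLength | 1 | residue count |
| physicochemical | 5 | mean hydrophobicity, mean hydropathicity (GRAVY), mean hydrophilicity, net integer charge, molecular weight (Da) |

Composition features deliberately span the full A–Z alphabet so rare
non-canonical letters (B, J, O, U, X, Z) are counted rather than silently
dropped.  The physicochemical block, by contrast, is strict by default and
raises on residues missing from its scales (a lenient mode excludes them
from the means).

The per-residue scales are a documented, swappable fixture: Eisenberg
consensus values for hydrophobicity, Kyte–Doolittle for hydropathicity,
Hopp–Woods for hydrophilicity, average residue masses with 18.02 Da added
for the chain termini, and an integer charge model at pH 7 (K, R = +1;
D, E = −1; histidine and all others 0 — the simplest convention that
yields integer-valued charge bins).  Databases differ in which scales they
tabulate; these defaults are a reasonable common choice, not a claim about
any particular source, and `ResidueScales` accepts alternatives.

The LZ76 variant is the exhaustive-history phrase count computed with the
Kaspar–Schuster scan (self-overlapping reproduction allowed; an incomplete
final phrase counts as one phrase), so `A^n` parses to 2 phrases for any
n ≥ 2.  Other Lempel–Ziv flavours can be slotted in behind the same
column.

## Descriptive statistics and hypothesis tests

For each numeric feature the stats stage produces class-conditional bin
counts (left-open/right-closed intervals; bin edges are configuration
inputs, since published break points are typically data-derived with no
stated rule), violin/QQ plot data with plotting positions (i − 0.5)/n, a
Shapiro–Wilk normality test (Royston approximation, 3 ≤ n ≤ 5000), and a
two-sided Wilcoxon rank-sum test between the classes.  The rank-sum test
uses midranks with tie and continuity corrections in its normal
approximation and switches to exact permutation enumeration when the
smaller sample has ≤ 10 observations and the enumeration is feasible
(≤ 5·10⁵ assignments).  Display output floors p-values at 2.2×10⁻¹⁶, the
conventional print floor.  No multiple-testing adjustment is applied at
this stage.

## Lasso feature selection

Selection maximizes the penalized log-likelihood

    L(β) = Σᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)] − λ Σⱼ |βⱼ|,
    pᵢ = σ(β₀ + xᵢ'β),

with an unpenalized intercept, over 100 log-spaced penalties from λ_max
(the smallest penalty zeroing every coefficient, `max_j |x_j'(y − ȳ)|`)
down to 10⁻⁴·λ_max.  Features are standardized first; zero-variance
columns are flagged and excluded.  The solver is a proximal-Newton
coordinate descent in the glmnet style: an outer loop builds the
iteratively-reweighted least-squares surrogate (probabilities clipped at
10⁻⁵ to keep weights positive), an inner loop runs cyclic soft-threshold
updates with an active-set strategy, and the path is fitted top-down with
warm starts.  The path stops early once a fit explains > 99.9% of the
null deviance — beyond that point smaller penalties only inflate nearly
unconstrained coefficients on (near-)separable samples at large cost.

λ is chosen to minimize 10-fold cross-validated mean binomial deviance
(stratified, seeded), with ties broken toward the sparser penalty.
"Selected" means |βⱼ| > 10⁻⁸ at the chosen λ.  Convergence is declared at
a maximum coefficient change below 10⁻⁵ per outer iteration; the companion
tests verify the subgradient (KKT) conditions directly and cross-check
coefficients against an independent solver (liblinear), which is why a
looser sweep tolerance suffices — demanding 10⁻⁷–10⁻⁸ offered no change
in the selected sets but a large constant-factor cost on the flat small-λ
tail.

## Classifiers

* **Logistic regression** — maximum likelihood via iteratively reweighted
  least squares.  If n ≤ p or (near-)separation is detected (a coefficient
  passing |β| > 30), a tiny ridge (10⁻⁸) on the non-intercept coefficients
  keeps the optimum finite, with a warning.
* **SVM** — soft-margin SVC (RBF kernel by default, γ = 1/p, C = 1; both
  exposed in configuration since published analyses rarely state them).
  Probabilities come from a Platt-style one-dimensional logistic
  calibration fitted on out-of-fold decision scores of the training data
  (5 inner folds, falling back to in-sample scores for very small
  classes).  The stored model keeps support vectors, dual coefficients and
  the intercept, so serialized models reload without refitting.  Only RBF
  and linear kernels are accepted.
* **AdaBoost** — discrete boosting over depth-1 threshold stumps, T = 100
  rounds by default.  Round t picks the stump minimizing the weighted 0–1
  error ε_t (ties broken toward the lowest feature index, then the lowest
  threshold, then positive polarity — fixed for bit-reproducibility), sets
  α_t = ½ ln((1−ε_t)/ε_t), and reweights instances multiplicatively.
  Boosting stops early at ε_t = 0 (stump kept, error floored at 10⁻¹²) or
  ε_t ≥ ½ (stump discarded).  The probability is σ(2·Σ α_t h_t(x)), the
  standard real-margin calibration of the additive score.

All three expose the same contract: `predict_proba` returns P(y = 1|x),
`predict` thresholds at 0.5 with ties going to class 1 (stated explicitly
because MCC and F1 depend on it), and `decision_scores` returns the raw
monotone score used for ROC construction.  A dual-efficacy flag marks
peptides with P(y = 1|x) ∈ [0.5 − δ, 0.5 + δ] (default δ = 0.1) as
candidates plausibly active against both diabetes types.

## Evaluation

Stratified 10-fold cross-validation refits the entire preprocessing chain
— standardization and lasso selection — inside every training fold, so no
test-fold information leaks into the model that scores it.  Inside
`cross_validate_all` the per-fold penalty search uses a 30-point grid down
to 0.05·λ_max with 5 inner folds: nested tuning needs only to rank
penalties, and this sizing reproduces the same selected sets as the full
grid at a fraction of the cost.  When a training fold selects no features
at all, the fold is scored by the intercept-only model (base-rate
probability, tied scores, fold AUC 0.5 by the ties convention) — the
honest prediction when selection reports no signal.

Out-of-fold predictions are pooled into one confusion matrix per method
(pooled totals equal the dataset size); per-fold AUC/ACC are retained for
fold-stability summaries.  ROC curves are built by threshold sweep over
decision scores rather than probabilities: the two orderings are
mathematically identical, but extreme fits can saturate probabilities to
exactly 0 or 1 in floating point, destroying the ranking.  The trapezoid
AUC equals the normalized Mann–Whitney U statistic with ties counted ½
(oracle-checked to 10⁻¹²).

Metric conventions, with the positive class always recorded: precision,
sensitivity and specificity are 0 when their denominator is 0; F1 is the
harmonic mean of the reported precision and sensitivity (0 when both are
0); MCC is 0 when any marginal is 0.  Because published 2×2 tables
sometimes follow a different orientation — and occasionally relabel
PPV/NPV as sensitivity/specificity — `orientation_report` emits the full
rate set under both positive-label conventions side by side.  ACC and MCC
are orientation-invariant and therefore the safest anchors for comparing
against printed tables; the regression fixtures in the test suite document
one published table whose sensitivity/specificity/precision only reproduce
as the PPV, NPV and sensitivity of the positive-label-0 orientation.

## Synthetic data generator

The generator emulates the statistical shape of a curated antidiabetic
peptide collection: 2281 peptides, 27% labelled class 1 (the fraction read
off published pooled confusion-matrix row totals, which are not fully
consistent across methods — an inference, flagged as such), class 0
shorter (discretized lognormal lengths, median 9.5, support 2–60, mode
near 9–10) and enriched in polar/charged residues, class 1 longer (median
9.5·1.9^effect_scale, slightly heavier tail) and enriched in I/L/V/F.
Residue frequencies are exponentially tilted along that hydrophobicity
axis.  A single `effect_scale` multiplies every class difference: 1 is
the default study condition, 0 gives exchangeable classes (null data) for
calibration checks.  Sequences use the 20 canonical residues;
`noncanonical_rate` optionally injects rare non-canonical letters to
exercise alphabet handling.

What the generator does *not* emulate: real residue autocorrelation along
sequences (residues are i.i.d. within a class), database-specific
curation artifacts, motif structure, or the true marginals of any real
collection.  Passing end-to-end tests on this data therefore demonstrates
that the pipeline machinery is correct and well-calibrated — not that any
particular real-data accuracy would be attained.

## Reference inputs

The published pooled confusion matrices used as regression fixtures for
the metric suite are 2×2 integer tables (dataset size 2281).  Their row
totals differ across the three methods even though the dataset is fixed;
the pooling or labelling behind that is not explained in the source and is
documented here rather than reproduced.  Published real-data AUCs, the
reported count of 432 selected features and the published p-value table
depend on the real database and unknown hyperparameters and are out of
scope as reproduction targets.

## Problem sizes and numerical choices

The end-to-end checks run the full n = 2281 pipeline (10 outer folds,
three classifiers) twice — default and null conditions — and a planted
recovery study (5 informative among 200 noise features, n = 500, 10
seeds, 50-penalty grid, 10-fold tuning); together these complete in a few
minutes on one CPU.  All randomness flows from explicit integer seeds;
repeated runs are byte-identical.  Degenerate inputs have defined
behaviour throughout: empty sequences and unknown residues raise typed
errors naming the offender, constant features are flagged and excluded
from penalized fitting, single-class ROC input raises, and a class with
fewer members than folds triggers an unstratified fallback with a
warning.

## Known limitations

* The generator's class differences are concentrated in length and
  global composition; features like AvgPositions and LZComplexity carry
  little synthetic signal, so their selection behaviour on real data is
  untested here.
* Platt calibration uses 5 inner folds on the training fold only; for
  very small folds it degrades to in-sample calibration.
* The lasso path's early deviance stop (99.9%) means the reported grid
  can be shorter than requested on strongly separable data; the truncation
  is recorded in the selection report.
* Pooled AUC concatenates out-of-fold scores from models fitted on
  different folds; score scales are comparable but not identical across
  folds.  Per-fold AUCs are reported alongside for that reason.
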