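# Methods

## Problem and model

The task is binary treatment assignment for femoral peripheral arterial
disease: medical management (coded −1) versus surgical or endovascular
revascularisation (+1), from 16 clinical features per patient. Features are
encoded onto a fixed numeric table: age/100 and embolism %/100 as
quasi-continuous slots; Fontaine stage, TASC lesion type, LDL category and
blood-pressure stage as small ordinal codes; the remaining findings as 0/1.
The printed code table assigns Fontaine I and II-a the same code 0 and skips
code 2 for TASC type C; both maps are implemented exactly as printed but are
exposed as module constants (`clinical_data.FONTAINE_CODES`,
`LESION_CODES`) so a user who considers those codes transcription slips can
rebind them.

The classifier is an RBF network with Gaussian hidden units
`Φ_j(x) = exp(−‖x−μ_j‖²/2σ²)` and a single linear output
`y = w₀ + Σ w_j Φ_j(x)`:

- **Centers** come from k-means on the training features. Default mode is
  batch (Lloyd) iteration; a sequential "online" mode that assigns one
  randomly ordered sample at a time and immediately recomputes the receiving
  center is provided as an alternative. Initial centers are k distinct data
  rows sampled uniformly (an axis-aligned bounding-box draw is available via
  `init="box"`). Convergence is max coordinate change < `tol` (default
  1e−6, `max_iter` 300). Nearest-center ties break to the lowest cluster
  index; an empty batch cluster is re-seeded with the sample farthest from
  its current center.
- **Spread**: all hidden units share one variance `σ² = η·d²/2`, with `d`
  the maximum pairwise center distance and `η = 0.6` by default. Per-unit
  variances are deliberately not implemented. Coincident centers (`d = 0`)
  raise an error rather than silently degenerating.
- **Weights** are the least-squares solution of `H·W ≈ y`, where `H` is the
  N × (n+1) design matrix with a leading all-ones bias column. We solve with
  a rank-revealing routine (`numpy.linalg.lstsq`), which equals the
  textbook pseudoinverse `(HᵀH)⁻¹Hᵀy` whenever `H` has full column rank;
  rank deficiency yields the minimum-norm solution with a logged warning.
  The explicit normal-equations formula is retained in the tests as an
  independent oracle.
- **Scores to decisions**: the raw score trained against −1/+1 targets is
  rescaled to `p = clip((y+1)/2, 0, 1)` so that a probability-like cutoff
  axis in [0, 1] applies. The network's cutoff field starts at 0.5 and is
  replaced after fitting by the Youden-optimal threshold of the **training**
  ROC. Deriving the cutoff from the training scores (rather than from the
  validation fold it will be applied to) keeps thresholded validation
  indicators unbiased: selecting the cutoff on the validation fold itself
  measurably inflates null-cohort accuracy (~0.60 against a 0.52 majority
  rate in our null experiments).

## Evaluation suite

Positive condition = the surgical decision (+1), so sensitivity is the
surgical-detection rate. Classification at threshold t uses the closed rule
`p ≥ t → positive`, which makes the ROC endpoints exact. The ROC sweeps the
thresholds {0} ∪ {observed scores} ∪ {1+ε} in descending order; AUC is the
trapezoidal area and equals the Mann–Whitney pairwise estimate (ties ½)
to machine precision. `optimal_cutoff` maximizes Youden's J with ties broken
toward the smallest threshold. Indicators with a 0/0 denominator are
reported as NaN flags, not exceptions.

The Hosmer–Lemeshow statistic uses deciles of predicted risk (10
quantile groups by default): `Σ_g (O₁−E₁)²/E₁ + (O₀−E₀)²/E₀` with
`E₁ = Σ p` in the group. Because least-squares scores are clipped into
[0, 1], an expected count can be exactly zero; denominators below 1e−10 are
replaced by a continuity floor of 0.5 expected counts, so a perfectly
confident correct group contributes 0 and a confident wrong one a large
finite penalty.

Fold summaries report mean, sample SD (k−1 denominator) and the 95 % CI
`mean ± 1.96·SD/√k`. The normal multiplier, not Student-t, is used: it is
the convention that reproduces the published interval arithmetic for k = 10
fold summaries (e.g. 0.950 ± 1.96·0.022/√10 → 0.936–0.964), which
t₀.₀₂₅,₉ = 2.262 does not.

Model comparison runs a two-tailed t-test per indicator at α = 0.05:
pooled-variance unpaired by default (the reporting convention the summary
tables imply — group means ± SD with no pairing language), with a paired
mode available since folds are in fact shared. Identical fold vectors give
t = 0, p = 1. No multiple-testing correction by default (10 indicators at
raw α); a Bonferroni flag is provided.

## Cross-validation protocol

Stratified k-fold (k = 10 default): within each class, shuffled indices are
dealt round-robin with a rotating offset, so per-class fold counts differ by
at most one and total fold sizes stay balanced (186 patients → folds of 18
or 19 with 8–9 medical and 9–10 surgical each). The hidden-node count is
selected by sweeping 2–50 and minimizing the mean validation MSE of raw
scores against the ±1 targets (the training objective); infeasible counts
are recorded as missing, and ties go to the smallest count. A single master
seed fixes the cohort, the fold plan, every k-means initialisation (per-fold
child seeds derive from `numpy.random.SeedSequence`), and therefore every
reported number.

## Synthetic cohort

The generator reproduces the demographic skeleton of the private study
cohort: exactly 186 records, 89 medical / 97 surgical, 114 men with ages
~N(53, 7²) and 72 women ~N(58, 5²) (truncated to (18, 100), integer years),
sex assigned independently of class by a seeded shuffle. Categorical
features are drawn class-conditionally: the medical class uses baseline
marginals chosen to give every category nonzero mass; for the surgical
class, category k (ordered by clinical severity) is re-weighted by
`exp(tilt_scale · class_effect · k / k_max)` and renormalised. The
exponential tilt was chosen over a linear re-weighting because the encoding
is fixed and bounded: a linear tilt can shift a binary feature's rate by at
most ~0.17, which caps the attainable class separation far below what a
strongly separable cohort requires, whereas the exponential family spans
the whole range from exact null (`class_effect = 0`, identical
distributions) to near-separability (`class_effect = 1`) and agrees with
the linear tilt to first order. Embolism %/100 is Beta(2, 6) for the
medical class and Beta(2 + 6e, 6 − 3e) for the surgical class. Defaults:
`class_effect = 0.5`, `tilt_scale = 3` — separable but not trivially
(cross-validated AUC ≈ 0.95, accuracy ≈ 0.86–0.88 on default seeds).

What the generator does **not** emulate: the real cohort's feature
marginals and inter-feature correlations (none were published), comorbidity
structure, or any site-specific selection effects. Passing tests on
synthetic cohorts therefore validate the correctness and calibration of the
pipeline — encoders, network algebra, resampling, statistics — not the
clinical performance figures attainable on real femoral-PAD records.

## Numerical and design notes

- k-means requires k ≤ number of distinct rows; k = that number drives WCSS
  to zero (each sample its own center).
- `fit_weights` tolerates rank deficiency (minimum-norm solution, logged);
  the interpolation regime (n_hidden = N with a tiny variance override)
  reproduces the labels to machine precision.
- The score→probability rescale `(y+1)/2` is one fixed affine choice for
  placing the cutoff axis on [0, 1]; published mean cutoffs near 0.5 are
  consistent with it.
- `summarize_folds` drops NaN (undefined-indicator) folds with a warning and
  requires at least two defined values.
- Problem sizes in the test-suite simulations (cohorts of 120–186, hidden
  units 4–29, sweeps to count 20, 100-run null-comparison batches) are
  chosen so the full suite completes in well under a minute of compute per
  heavy test while keeping each check's sampling error far below the margin
  it asserts.
- Known limitation: with a Youden-balanced cutoff the no-signal expectation
  of accuracy is ~0.5 rather than the majority-class rate; for class
  proportions 89/97 the two reference points differ by ~0.022, which
  matters when checking null calibration against the majority rate at high
  precision (see the null-calibration tests).
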