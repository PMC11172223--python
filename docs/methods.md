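# Methods

`libspect` implements a three-stage classification method for broadband
laser-induced breakdown spectroscopy (LIBS) spectra — Gaussian smoothing,
stacked relevance/redundancy channel selection, and a precision×recall
weighted fusion of three light classifiers — together with the synthetic
spectrum generator used to exercise it. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## The classification problem

A broadband LIBS spectrum is a vector of tens of thousands of intensity
values over a 200–975 nm wavelength axis. Elemental composition shows up as
sparse emission lines; almost everything else is continuum and
high-frequency noise. Classifying specimens (here: plant varieties whose
elemental profiles differ) from such spectra faces three obstacles: noise,
extreme dimensionality with few informative channels, and the limits of any
single classifier's mapping rule. Each pipeline stage addresses one of
them.

## Stage 1 — Gaussian smoothing

Each spectrum is convolved with a discrete Gaussian kernel
`w_x ∝ exp(−x²/2σ²)`, `x = −(m−1)/2 … (m−1)/2`, renormalized to sum to one
(the continuous `1/√(2πσ²)` prefactor cancels under renormalization, which
also makes the weight sum exact on finite support). Defaults `m = 5`,
`σ = 1.5` channels — the conventional small window for line spectra: wide
enough to suppress single-channel noise, narrow enough (±2 channels) to
leave 6–9-channel line profiles essentially in place.

Boundaries are reflect-padded. The paper-style alternative — truncating and
renormalizing at the edges — was rejected because reflect padding keeps two
exact identities that the tests rely on: a constant spectrum is a fixed
point, and interior values of a linear ramp are unchanged. Smoothing is a
convex combination per output channel, so it can never extend a spectrum's
range; on pure white noise it strictly reduces variance (the squared kernel
norm is < 1 for m > 1).

## Stage 2 — stacked channel selection

**Relevance.** Every channel X is scored against the class label Y with a
normalized mutual information

    MIC(X, Y) = I(X; Y) / √(H(X) · H(Y)) ∈ [0, 1],

after discretizing X into equal-frequency (quantile) bins. The √-product
normalization guarantees the [0, 1] range (1 for an injective
deterministic relationship, 0 at either degenerate marginal); dividing by
the plain product H(X)·H(Y) is available via `denominator="product"`. The
discretization is a free parameter of any histogram MI estimator; the
default `bins = min(16, ⌈√n⌉)` keeps expected cell counts workable at small
n while capping estimator variance at large n, and quantile edges make the
score invariant to monotone intensity transforms and robust to the heavy
right skew of emission intensities. Channels are ranked by score, ties
broken toward the lower channel index; scores are also banded into
strong (≥ 0.6), moderately strong (≥ 0.4), weak (≥ 0.2) and extremely weak
(< 0.2) for reporting — conventional correlation-strength cutoffs,
configurable and carrying no algorithmic weight.

**Redundancy.** Neighbouring channels sampling one emission line are
near-perfectly monotonically related, so top-k relevance selection alone
returns clumps of duplicates. A greedy pass over the top-k channels in
descending score order keeps a channel only if its absolute Spearman rank
correlation with every already-kept channel is ≤ τ. Greedy-by-relevance
means each redundant clump is represented by its most label-relevant
member; |ρ| is used because anti-correlated channels are equally redundant.
One boundary rule: a perfect monotone duplicate (|ρ| = 1) is pruned at any
τ, including τ = 1 — it can never add information, and this keeps "τ = 1
removes exactly the duplicates" true. Spearman rather than a second MI pass
because the k² pairwise stage needs a cheap, tie-robust, nonlinear-capable
statistic; Pearson-on-average-ranks is used throughout, which equals the
classical 1 − 6Σd²/(n(n²−1)) form exactly when ties are absent. A constant
channel has no rank ordering; its correlation is reported as 0 with a
warning rather than NaN so that greedy pruning remains total.

**Tuning.** Both k and τ are set by validation-accuracy grid search
(defaults: k over 50–1000 step 50 when searched, τ over 0.80–0.99 step
0.01), scoring a standardized RBF-SVM on the validation split. Ties go to
the smaller k, and for τ to the fewer surviving features — the economy
direction is the point of the stage. The fitted pipeline defaults use fixed
k = 300 and τ = 0.9 so that a default fit stays cheap; `top_k=None` /
`spearman_threshold=None` switch the searches on.

## Stage 3 — weighted fusion

Three sub-models — an RBF-kernel SVM and a 5-NN classifier behind
per-channel standardization, and a 200-tree random forest — are fitted
independently on the training split ("parallel" is a throughput notion
only; results are order-invariant by construction). Each sub-model i gets
per-class precision P_i[c] and recall R_i[c] measured on a weight split,
and votes with weight

    W[i, c] = P_i[c] · R_i[c]      (no normalization).

Sub-model outputs are one-hot hard labels Z_i; the fused score of class c
is Σ_i W[i, c] Z_i[c] and the argmax wins. Exact ties fall to the
prediction of the sub-model with the best macro-F1 on the weight split — a
deterministic, defensible rule. A soft mode (Z_i = predicted class
probabilities) exists behind `score_mode="soft"` but the hard mode is
canonical.

Two genuinely open choices, both kept switchable:

* **Where P, R are measured.** Training-set metrics of a random forest are
  degenerately ≈ 1, which collapses W to near-uniform; the canonical mode
  therefore measures them on the validation split (`weight_mode="train"`
  restores the training-set reading).
* **Sub-model hyperparameters.** Defaults are fixed documented values
  (SVM C = 10, γ = "scale"; forest 200 trees; 5-NN); `tune=True` (the
  pipeline default) grid-searches each sub-model's small documented grid by
  validation accuracy.

A single sub-model with nonzero weights reduces fusion exactly to that
sub-model; raising W[i, c] can never flip a prediction away from class c.

## Evaluation

Stratified 60/20/20 train/validation/test tagging (largest-remainder
apportionment per class, seeded shuffle); stratified k-fold
cross-validation (default 5); confusion matrix with per-class precision as
the bottom margin, per-class recall as the right margin and overall
accuracy in the corner; accuracy plus per-class and unweighted-macro
precision/recall/F1. With the balanced default design, macro and weighted
averages coincide; macro is stated for definiteness. A never-predicted
class has precision 0 and is flagged. Baselines: the three single
classifiers on all channels, optionally behind a PCA retaining 95% of
training variance — fitted on the training split only, as is every
transform; no fit ever sees test-tagged rows.

## The synthetic generator

No public LIBS dataset backs this method, so the generator is the testbed
and defines the benchmark conditions. A spectrum is

    baseline + Σ_lines factor[class, line] · amplitude · G(λ; center, width)
    + N(0, noise_sd²) + N(0, (shot_scale · signal)²)

on a 200–975 nm axis. Defaults: 4000 channels (a paper-scale ~27,000 axis
is one config change but tests do not need it), 40 Gaussian lines of width
0.3 nm — 30 placed in 350–800 nm, where characteristic lines of plant
material concentrate, 10 elsewhere — amplitudes 300–3000 over a baseline of
100, white-noise sd 60, shot-noise scale 0.2, 10 classes × 90 spectra
(mirroring 3 pellets × 30 accumulations per variety).

Class structure: classes come in similarity *pairs*. Each pair shares a
lognormal base factor vector (log-sd 0.25) and its two members differ by a
further lognormal perturbation whose log-sd cycles through
(0.03, 0.05, 0.08, 0.12, 0.2). This makes some variety pairs nearly
confusable and others easy — the heterogeneous per-class difficulty that
real varieties show and that per-class fusion weights exist to exploit.
Noise levels were calibrated once so that single classifiers on selected
channels score in the high-0.80s to mid-0.90s, the regime reported for real
LIBS variety classification; they are not tuned per experiment. All
stochastic draws flow from one `default_rng(seed)` stream, so identical
config + seed is bit-identical.

What the generator does **not** emulate: real elemental line positions or
physical plasma effects (self-absorption, matrix effects, line broadening
changes), correlated per-shot intensity jitter, baseline drift, wavelength
miscalibration, or sample-to-sample within-class composition variation
beyond the noise model. Consequences for interpretation: passing tests show
the pipeline recovers known class-informative channels and combines
classifiers as designed; they do not show field performance on real
spectra. In particular, sub-model error patterns on synthetic classes are
more correlated than the strongly model-specific per-variety patterns
reported on real data, so the fusion model here tracks its strongest
sub-model closely (ties within ~1 point) rather than exceeding it — the
per-class complementarity that drives real gains is only weakly present.

## Numerical and degenerate-input choices

* Kernel weights renormalized after discretization; weight sum exact to
  1e-12. Extreme size/σ ratios underflow outer taps to exact 0 and are
  outside the supported envelope.
* MIC is clipped to [0, 1] against floating-point overshoot and defined as
  0 when either marginal entropy is 0.
* Quantile binning sends ties to one bin; heavily tied channels may occupy
  fewer bins than requested.
* Rank correlations computed via standardized average ranks; a constant
  column correlates 0 with everything (warning).
* Grid searches: first-maximum (smallest k) and fewest-features (τ)
  tie-breaks; a k grid reaching past the channel count is truncated with a
  warning.
* t-SNE diagnostics: perplexity 30 (capped below the sample count), PCA
  initialization, fixed seed; per-class marginal normal curves use the
  sample mean/sd per embedding axis on a shared density scale.
* Workflow JSON artifacts are serialized with sorted keys; reruns with one
  config + seed are byte-identical. Fitted sub-model state lives in a
  joblib sidecar referenced from `model.json`.

## Problem sizes used in the checked experiments

The test suite exercises compact geometries (3–5 classes, 300–1200
channels) for unit and property checks, and the full default benchmark
(10 × 90 × 4000, 20 seeds) for the fusion-dominance and selection-economy
properties; `scripts/acceptance.py` runs the full benchmark, its noiseless
variant, and the 20-seed median comparison. These sizes are the package's
chosen benchmark conditions; everything scales to larger axes through the
config.

## Known limitations

* The MIC here is histogram-normalized mutual information, not the
  grid-partition MIC estimator of the statistics literature; the
  normalized-MI reading is deliberate and canonical for this package.
* Hard-vote fusion cannot out-score its best sub-model when the weaker
  sub-models' errors are strongly correlated (see the generator section).
* Redundancy pruning is greedy, not optimal subset selection; it guarantees
  the pairwise constraint, not minimality.
* Validation-based weights and tuning reuse one validation split; with 18
  samples per class the weight estimates are coarse.
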