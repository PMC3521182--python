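# Methods

## Rank representation

Each sample's expression vector is replaced by its within-sample ranks:
ascending (lowest expression → rank 1), ties averaged, so the rank sum per
sample is always G(G+1)/2 for G features. Average ties match the Wilcoxon
convention used elsewhere in the package and make the transform exactly
invariant under strictly increasing per-sample maps. Ranks are raw (1..G) by
default; a `normalize` flag divides by G, which only rescales distance- and
margin-based classifiers.

Ranks are computed on the **full** feature set before feature selection: a
test instance's representation must not depend on which features a
particular training run selected. The alternative (rank over the selected
features only) is available by ranking a pre-subset matrix, for sensitivity
analysis, but is not the default pipeline.

## Feature selection

Two univariate tests score each gene on training data only:

* `ttest` — classic pooled-variance two-sample t (Welch behind a flag). A
  zero pooled variance is flagged degenerate with p = 1: a constant gene is
  uninformative, not an error.
* `wilcoxon` — rank-sum W of the positive group on pooled average-tie ranks,
  two-sided p by normal approximation with tie and continuity corrections.
  The approximation keeps per-gene scoring cheap if selection is re-run per
  bag; the test suite cross-checks it against an exact permutation null.

Selection takes the top k by ascending p-value, ties broken by descending
|statistic| then feature ID, so the chosen set is deterministic. k defaults
to 100 (typical published signature sizes); the scenario harness exposes it.
Selection runs once per training set by default — selection and bagging are
treated as separate stages; re-selecting per bag is possible by ranking a
pre-subset matrix but is not a pipeline default.

## Sequential ensemble sizing

For a test instance T, bootstrap bags of m training samples are drawn with
replacement (single-class bags are redrawn, up to 1000 times); a base
classifier trained on each bag casts a Boolean vote (probability score
≥ 0.5). The vote stream drives a Wald sequential probability ratio test of
H0: p ≤ θ−δ against H1: p ≥ θ+δ with defaults θ = 0.5, δ = 0.1,
α = β = 10⁻⁴, n_max = 100, n_min = 1. The log-likelihood ratio moves by
log((θ+δ)/(θ−δ)) per positive vote and log((1−θ−δ)/(1−θ+δ)) per negative
one; H1 is accepted at log((1−β)/α) ≈ 9.21, H0 at log(β/(1−α)) ≈ −9.21.
With the defaults an unbroken positive stream accepts after exactly
⌈9.2102/0.4055⌉ = 23 votes. At the cap with no decision, the majority of
votes decides and an exact tie goes negative — any fixed rule suffices,
because AUC is computed from the mean member score, not the Boolean
decision. Inside the indifference region (θ−δ, θ+δ) the test guarantees
nothing; outside it the error rates are bounded by α and β.

δ is a free parameter here: the guarantees (and minimal expected sample
size) are those of Wald's SPRT with an indifference region; narrower δ
buys resolution near θ at the cost of longer vote streams.

Per-instance randomness is seeded from (master seed, sample ID), so each
test instance's result is independent of the test set's composition and
order — the property that lets the method classify single incoming samples.
In fixed-size bagging (the 10- and 100-bag comparison arms) one shared
ensemble is trained and applied to all instances; with n_bags = 1 and
bootstrapping disabled it degenerates to the no-bagging baseline.

### Base classifiers

* `svm` — linear-kernel SVC; score = logistic squash expit(margin). The
  squash is monotone in the margin and agrees with the 0.5 decision cut, so
  votes equal the SVM's own predictions while scores stay graded.
* `knn` — k-nearest neighbours, K = 5 (reduced for tiny bags); score = vote
  fraction.
* `tree` — CART decision tree; score = Laplace-smoothed leaf class frequency
  (n⁺+1)/(n+2), keeping scores off hard 0/1 so ensemble means remain
  informative.

## Clean-bag enrichment theory

`theory` implements the binomial argument above: the exact pmf (scipy's
log-space binomial, safe for large m), the tail advantage
P_B(&lt;x) − P_B(&gt;x), and the skewness (1−2q)/√(mqp) whose sign
(positive iff q < 1/2) drives the argument. `simulate_bag_quality` is the
independent oracle: it draws actual index multisets and counts bag
contamination, never touching the closed form it validates. The advantage is
strictly positive for every minority contamination (swept exhaustively to
m = 200) but is capped well below 1 at integer x by the tie mass P_B(x);
the limit toward 1 as p → 1 applies to the continuous curve where the
threshold mq falls strictly between integers.

## Evaluation harness

AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted half (scikit-learn's implementation,
verified exactly against O(n²) pair counting). AUC changes against the
absolute-value no-bagging baseline are categorised with the ±0.05
thresholds, boundaries inclusive toward the "slightly" categories
(Increased > 0.05; 0 ≤ IncreasedSlightly ≤ 0.05; −0.05 ≤
DecreasedSlightly < 0; Decreased < −0.05); the measured change is snapped
to 12 decimals first so an exact ±0.05 lands on its boundary category.

A scenario grid crosses datasets × {forward, backward} × {ttest, wilcoxon}
× {svm, knn, tree} × training-subset fractions × method arms
({baseline_absolute, rank, bag10, bag100, dynamic}). Stratified subsampling
(per-class counts round(fraction × class size), at least 1, without
replacement) is applied to the training batch only. Negative-control
datasets are excluded from improvement statistics and reported as a raw AUC
distribution.

## Synthetic data

The generator emulates two-batch expression studies at desk scale:

* per-gene log2-scale baselines, mean ~ N(7, 1.5²), sd ~ U(0.5, 1.5)·noise_sd
  — heterogeneous genes, as on real arrays;
* `n_informative` genes shifted between classes by `effect_size` gene-sds
  (a per-gene Cohen's d), random sign per gene;
* the test batch distorted per sample by a + b·f(x): affine jitter around
  the configured shift/scale centres (sd 20%) composed with an optional
  strictly monotone warp f (cube, exp, or a random increasing
  piecewise-linear map). Every distortion is strictly monotone per sample —
  exactly the regime the rank representation neutralises, and the rank
  matrices of distorted and undistorted batches are bit-identical;
* `bad_fraction` q of training labels flipped (default operationalisation of
  "bad" samples; an alternative mode leaves labels intact and multiplies
  those samples' noise ×10), with q < 1/2 enforced;
* a negative-control mode: labels uniformly random, class signal zeroed.

Severity presets low/medium/high (affine-only → +cube → +exp with growing
shift/scale) loosely mirror the increasing batch-effect severity of the
emulated cohorts; `emulate_paper_sizes("A"|"D"|"F"|"I")` reproduces the
published cohort sizes and class ratios (e.g. A: 70 training samples with
26 positives, 88 validation with 28; I is the random-label negative
control).

What the generator does **not** emulate: probe-level measurement physics,
correlated gene modules, batch effects that scramble within-sample gene
order, or class-ratio drift beyond the configured train/test ratios. Tests
passing on this generator show the pipeline is rank-invariant, calibrated
and noise-tolerant under the method's stated assumptions — not that any
particular clinical AUC will be achieved when those assumptions fail.

## Problem sizes and experiment conditions

Grid experiments (tests and the acceptance script) run three synthetic
datasets (two medium, one high severity) with G = 400 genes,
40 informative, 60 training / 50 test samples per batch, q = 0.1 flipped
training labels, k = 30 selected features — 36 scenario cells per grid.
These sizes keep a full grid to a couple of minutes on one CPU while
leaving each cell enough samples for stable AUCs. The sequential-test error
simulation uses 2×10⁵ vote streams per regime; the bag-quality oracle uses
10⁵ bags per (m, x).

## Known limitations

* The sequential test's guarantees apply to the vote probability, not
  directly to classification error; inside the indifference region the
  decision is honest but unguaranteed.
* Bags are drawn per test instance in dynamic mode; classifier work is not
  shared across instances (deliberate — it preserves per-instance
  independence; fixed-size arms amortise instead).
* The Wilcoxon p-value is asymptotic; for pooled group sizes below ~10 its
  p-values are approximate (the statistic and ordering are exact).
* Collapse-to-gene uses the per-sample probe maximum only; no alternative
  summaries (mean, median-polish) are provided.
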