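# Methods

This note records the models implemented in `lungct`, the defaults and why
they were chosen, what the synthetic phantoms do and do not emulate, and
the numerical and design decisions a maintainer would want to know.

## Synthetic phantoms

Each phantom is a 2-D grayscale image in [0, 1]: a soft-tissue background
(0.55) with two dark elliptical lung fields (0.20, semi-axes 0.32/0.17 of
the image size) and, for cancerous samples, one or more bright tumor blobs
— rotated ellipses with aspect ratio 0.7–1.0 whose intensity sits +0.2 to
+0.5 above the lung-field gray. Tumor centers are rejection-sampled so the
blob fits entirely inside a lung ellipse; a radius that cannot fit raises
a configuration error. Gaussian noise (σ = 0.03) is added and clipped
first, then salt-and-pepper impulses (density 0.02) overwrite pixels with
0 or 1, so the true impulse extremes survive for the median-filter stage.
The image-level label is *cancer* iff at least one tumor was planted, and
the mask is exactly the union of rasterized blobs.

`PhantomConfig` defaults to 240×240 pixels, matching the resolution
typical of the resized clinical CT slices this pipeline family targets.
The benchmark pipeline uses 64×64 phantoms with tumor radii 4–9 px — the
same relative nodule-to-lung scale — so a full 400-image run with
training, tuning and evaluation completes in well under a minute.

Datasets are generated with a chosen prevalence and stratified
train/validation/test splits (largest-remainder allocation, per-class
fractions supported so the reference study design's class-by-split counts
can be emulated exactly). All randomness flows from one integer seed;
identical seeds give byte-identical datasets.

**What the phantoms do not emulate:** anatomy (airways, vasculature,
mediastinum), CT acquisition physics (beam hardening, reconstruction
kernels, HU calibration), 3-D structure, inter-scanner variation, and
tumors that touch the lung boundary or pleura. Passing the benchmark
therefore demonstrates that the pipeline's machinery is correct and that
it can exploit intensity/shape separability — not that it would reach
similar numbers on clinical CT.

## Preprocessing

* `median_filter3` — plain 3×3 median with zero padding (the padded
  neighborhood is sorted ascending and the center element taken).
* `average_filter` — k×k mean, zero padded, so border means include the
  padding zeros.
* `adaptive_median_filter` — standard two-stage scheme: for each pixel the
  window grows 3, 5, … s_max while the window median is an impulse
  (min = med or med = max); once it is not, the pixel itself passes
  through unless it is an impulse, in which case the median replaces it.
  Implementation is vectorized per window size with min/median/max rank
  filters. Note the filter is *not* the identity on arbitrary noisy
  images: pixels equal to their local window extremes are treated as
  impulses by design; it is the identity on smooth ramps.
* `histogram_equalize` — levels map through the image CDF,
  k → round(CDF(k)·(N−1)), N = 256 by default; float images in [0,1] are
  quantized to N levels first. Exact halves round *down* (0.5·255 → 127),
  a fixed convention so equalized outputs are platform-reproducible.

Pipeline order: adaptive median (s_max = 7) → average (k = 3) →
equalization. Filtering precedes equalization so the equalizer does not
amplify impulse noise.

## Deep-belief-network segmenter

Patches of 16×16 pixels are standardized per-pixel (training-set mean/sd).
The stack is GB-RBM (256→128) then BB-RBM (128→64); continuous pixels
enter the Gaussian-visible layer first. Energies:

* BB: E(v,h) = −Σᵢⱼ Wᵢⱼvᵢhⱼ − Σᵢ aᵢvᵢ − Σⱼ cⱼhⱼ
* GB (unit variance): E(v,h) = ½Σᵢ(vᵢ−aᵢ)² − Σⱼ cⱼhⱼ − Σᵢⱼ vᵢWᵢⱼhⱼ

with conditionals P(hⱼ=1|v) = σ(ΣᵢvᵢWᵢⱼ + cⱼ) and P(vᵢ=1|h) = σ(ΣⱼWᵢⱼhⱼ + aᵢ)
(GB visibles: Gaussian with mean ΣⱼWᵢⱼhⱼ + aᵢ). Biases are named
`b_vis`/`b_hid` and wired exactly as the conditionals require. Exact
partition functions and joint probabilities are available for models up to
20 total units (full enumeration; GB needs an explicit discretized visible
grid) and back both the unit-test oracles and the exact-NLL training
monitor.

Pretraining is CD-1 with mean-field reconstructions and Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, batch 64, 10 epochs — the network's training
configuration; the "momentum 0.9" knob is Adam's β₁). Weights initialize
at scale 1/√n_visible so initial hidden pre-activations are of unit order.

Supervision: a patch's label is the ground-truth mask value at its center
pixel. After greedy pretraining the stack's weights seed a sigmoid
feed-forward network with a logistic output, fine-tuned end-to-end by Adam
for the same 10 epochs. *Design note:* a logistic head on frozen
pretrained features was evaluated first and could not separate
tumor-center patches (the discriminating rule "bright center AND dark
surround" is not linearly expressible in near-random sigmoid features;
patch-level performance capped mean Dice near 0.3), so the package uses
the canonical DBN recipe — pretrain, then backpropagate through the whole
stack. Training patches are harvested at stride 2 for label diversity;
all tumor patches are kept and background patches subsampled to twice
their number (at least 500), capped at 20 000 patches.

Segmentation slides the 16×16 window at stride 4, writes each patch
probability into its central 8×8 block, averages overlapping
contributions (border pixels missed by central blocks fall back to
full-patch coverage), and thresholds at 0.5. The central-block assembly
localizes predictions better than painting whole patches; stride-4
assembly bounds achievable Dice at roughly 0.8 on 4–9 px tumors even with
a perfect patch classifier, which is why the benchmark criterion sits at
0.70.

## Feature catalogue

Exactly 50 named features (order frozen in `FEATURE_NAMES`): 5 population
moments (mean, variance, sd, skewness m₃/m₂^{3/2}, excess kurtosis
m₄/m₂²−3) of the segmented region and of the whole image; a 16-bin region
intensity histogram; 8 shape descriptors of the mask treated as one
(possibly disconnected) region — area fraction, perimeter, eccentricity,
solidity, extent, major/minor axis, compactness 4πA/P²; 8 gray-level
co-occurrence statistics (32 levels, distance 1, horizontal, symmetric,
normalized: contrast, dissimilarity, homogeneity, ASM, energy,
correlation, entropy, max probability) on the region bounding box; and 8
Sobel-gradient statistics (region mean/sd/max/p90, image mean/sd, region
and image edge density at |∇| > 0.1). Zero-variance regions report
skewness and kurtosis as 0; an empty mask is an explicit error — the
pipeline substitutes the whole-image mask when a (typically non-cancer)
image yields an empty segmentation, so its feature vector describes the
global intensity distribution instead.

Only the five first-order moments are canonical to this pipeline family;
the remaining 45 are this package's fixed catalogue, chosen to give the
selector a realistic mixed search space of intensity, shape, texture and
edge information.

## Spiral + rough-set feature selection

Features are discretized into 4 equal-frequency bins (edges fit on
training data). The dependency degree γ(B) = |POS_B(d)|/|U| uses the
positive region — the union of B-indiscernibility classes contained in a
single decision class. γ is monotone under attribute addition and equals
1 iff the table is consistent w.r.t. B.

The spiral search runs m = 30 points in [0,1]ⁿ for k_max = 100
iterations: x ← c + r·R(x−c) about the incumbent best, with R the n×n
block rotation [[0ᵀ,−1],[I,0]] (orthogonal, period 2n). Two step-rate
schedules are exposed: constant r = δ^{1/k_max} (periodic descent;
δ = 10⁻³ or 1/k_max) and the convergence schedule r = 1 for
k* ≤ k ≤ k*+2n−1, else δ^{1/(2n)} with δ = 0.5, where k* tracks the last
improving iteration. The convergence schedule with δ = 0.5 is the
default. Initial points are rejection-sampled until the spans of rotated
pairwise differences are full-rank. Points binarize at 0.5 (an empty
subset is repaired by activating the coordinate nearest 0.5) and are
scored by 0.9·γ(B) + 0.1·(1−|B|/n).

After the search, backward elimination drops attributes (highest index
first, repeated to a fixed point) whose removal preserves the full-table
γ; the same reduction applied to the full attribute set provides a
deterministic second candidate, and the higher-fitness of the two is
returned. Consequently the returned subset always satisfies
γ(B) = γ(full) and is minimal by inclusion. On tables with a unique
minimal reduct this recovers it almost always; with multiple reducts the
spiral decides which one.

**Small-sample caveat:** with fewer than ~150 objects and 4-bin
discretization, random attribute pairs are frequently decision-pure by
chance (γ saturates at 1), so selection — and downstream classification —
degrades on very small runs. The benchmark's 200 training samples are
comfortably above this regime.

## GOSS gradient boosting

Binary logistic-loss boosting, F ← F + lr·tree, lr = 0.1, base score the
training log-odds. Per round, GOSS keeps the ⌈b·o⌉ largest-|gradient|
instances (weight 1) and ⌈c·o⌉ uniform draws from the rest (weight
(1−b)/c; defaults b = 0.2, c = 0.1), making sampled gradient sums
unbiased. Trees grow leaf-wise, always splitting the leaf with the
largest sampled variance-gain improvement; candidate thresholds are 32
equal-frequency histogram bin edges per feature. Constraints enforced on
the full training rows routed through the tree: every leaf ≥ MDL rows,
depth ≤ MD, leaves ≤ NL. Leaf values are weighted Newton steps
−Σw·g/(Σw·h + 10⁻⁶). Exclusive feature bundling is a documented no-op:
the 50 dense features have no mutually exclusive sparsity to bundle.

Hyperparameter grids: MDL ∈ {20, 40, …, 240}, NTI ∈ {10, 20, …, 450},
NL ∈ {20, …, 256}, MD ∈ {1, …, 12}. The Harris hawks tuner searches
continuous [0,1]⁴ positions projected to the nearest grid points,
minimizing 1 − mean stratified-CV accuracy (3 folds). On benchmarks too
small for a grid MDL, both the CV objective and the final fit clamp MDL
to half the available rows so the root can still split; reported
parameters remain grid points.

## Harris hawks optimizer

Canonical phase logic driven by escape energy E = 2E₀(1 − t/T),
E₀ ~ U(−1,1): exploration when |E| ≥ 1 (random-hawk or rabbit−mean
moves), otherwise soft/hard besiege, with Lévy-flight (β = 1.5) rapid
dives on the r < 0.5 branches; positions clip to bounds. On top, an
elite-mutation step perturbs the best 10% of hawks with Gaussian noise of
scale 0.1·(range)·t^{−1/2}, accepted only on improvement, so the
incumbent never worsens. Exploitation moves are accepted greedily;
exploration moves unconditionally.

## Pipeline and evaluation

Stages run generate → preprocess → segment → extract → select → tune →
train → evaluate, each seeded from one master seed; every stage except
classification can be toggled for ablation. Tuning cross-validates on the
training split; the final classifier refits on train+validation and is
evaluated on the untouched test split. Metrics come from the confusion
matrix with cancer as the positive class; zero-denominator ratios are
reported as 0 with a warning flag rather than NaN. ROC points are
computed at every distinct score threshold (ties enter simultaneously)
with trapezoid AUC. Mean Dice is taken over test images whose
ground-truth mask is non-empty (Dice is 0/0 on empty-vs-empty);
`dice_coefficient` itself defines that degenerate case as 1. Reports
serialize to canonical JSON with wall-clock timings excluded, so
identical seeds give byte-identical reports.

Benchmark sizes: 400 phantoms at 64×64 (0.5/0.2/0.3 split, prevalence
0.5), tuner budget 5 hawks × 6 generations. These sizes make the whole
benchmark, including two determinism runs, complete in about a minute on
one CPU core while leaving every stage with enough data to function.

## Known limitations

* Phantom realism (above): results bound pipeline correctness, not
  clinical performance.
* The stride-4 patch assembly quantizes mask boundaries; very small
  tumors (< 4 px radius) may be missed outright.
* Rough-set selection overfits tables with few objects (γ saturation).
* The GBDT is a faithful but compact reimplementation: no feature
  bundling, no missing-value handling, binary classification only.
* HHO, like all metaheuristics here, is seeded for reproducibility;
  different seeds can return different (equally grid-feasible)
  hyperparameters.
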