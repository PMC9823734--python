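# Methods

`eegemotion` classifies the emotional state (negative / neutral / positive)
of short EEG recording segments from tables of pre-extracted statistical
features, the format consumer headbands such as the Muse (electrodes TP9,
AF7, AF8, TP10) export after on-device windowed feature extraction.  The
pipeline is: min-max scaling → attention-residual CNN feature extraction →
correlation-matrix PCA with cumulative-contribution component selection →
classification by a Modified Random Forest (M-RF), with Gaussian Naive
Bayes, an information-gain decision tree and k-nearest neighbors as
internal baselines.

## Data model and splitting

A `FeatureTable` is an n×p matrix of finite unitless features with one
emotion label per row.  Labels are encoded negative=0, neutral=1,
positive=2 everywhere.  The train/test split is stratified 80:20 by
default and seeded.  Per-class test quotas are allocated by the
largest-remainder method, so the total test count equals
round(n·(1−train_fraction)) exactly while class proportions are preserved
up to rounding; with 1070 balanced rows this yields the 214-segment test
set that all of the package's worked confusion-matrix examples total to.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
raw EEG.  Features come in equicorrelated Gaussian blocks (block size 8,
within-block correlation 0.5 by default) because windowed statistics from
the same electrode co-vary; blocks are assigned to classes disjointly and
each class receives a mean shift of `separability` within-class standard
deviations on its own blocks, so every class has discriminative features.
Defaults are 200 segments per class and p=64 features — the scale at which
all recovery experiments here are run.  What the generator does **not**
model: non-Gaussian feature marginals, temporal autocorrelation between
segments, subject effects, artifacts, or class imbalance.  Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and calibrated, not that real headband data will reach any
particular accuracy.

At separability 0 the three class-conditional distributions are identical
and every classifier must land in the 3-class binomial chance band; at
separability 6 the classes are linearly separable and a nearest-centroid
oracle reaches ≥0.99 accuracy, a bar the full pipeline must match.

## Feature scaling

Min-max scaling of each feature to (x−min)/(max−min), fit on training data
only.  Constant training columns map to 0.  Out-of-range test values are
not clipped: a segment outside the training envelope carries information a
downstream tree can use.  Z-scoring is not done here — standardization is
part of the PCA recipe.

## Attention-residual CNN extractor

The p features of a segment are treated as a length-p one-channel 1-D
signal.  The trunk is `n_dense_blocks` (default 3) dense blocks; each
convolution unit is a same-padded width-3 convolution, a per-channel
activation normalization over positions, and a ReLU, with unit outputs
concatenated onto the block input so channels grow by `growth_channels`
(default 16) per unit.  "Normalized" is read as this per-unit activation
normalization; because it is computed per sample (instance-wise), inference
is batch-independent and deterministic.

The attention block refines the stacked features: a trunk branch (one
convolution unit) produces a map OF, a mask branch (pointwise convolution
followed by a sigmoid) produces N ∈ (0,1), and the combination is the
attention-residual rule

    AM = (1 + N) ⊙ OF,

whose defining property is that a zero mask passes the trunk features
through unchanged instead of gating them to zero — this is what lets
attention modules stack without destroying signal.  The plain ResNet
combination AM = a + OF(a) is available (`attention=False`) as the
comparison configuration; an ablation test checks that the attention path
is never materially worse on separable data.  The trunk input of the
attention block is taken to be the dense-stack output (the block input),
one of several layouts consistent with the combination rule; it is the
simplest that keeps mask and trunk shapes aligned.

Global average pooling over positions, a linear projection to
`embedding_dim` (default 64) with ReLU, and a linear softmax head complete
the network.  Training is minibatch Adam on multiclass cross-entropy
(default 30 epochs, learning rate 3e-3, batch 32), chosen for reliable
desk-scale convergence: at these defaults the network reaches ≥0.99
training accuracy on separable synthetic data.  After training, the pooled
penultimate activations (not the softmax head) are emitted as features for
PCA.  The network and its training loop are implemented directly on numpy
with a small reverse-mode autodiff tape (`_autodiff.py`); gradients are
pinned by finite-difference checks in the test suite, and seeded
single-threaded runs are bit-reproducible.

## PCA with cumulative-contribution selection

The recipe is deliberately the classical correlation-matrix one:
standardize each column with its sample standard deviation (n−1), form
K = GᵀG/(n−1), eigendecompose, convert eigenvalues to contributions
β_i = γ_i/Σγ and cumulative contributions CC_i, and retain the smallest m
with CC_m ≥ threshold (default 0.85).  Numerical conventions: eigenvalues
are clipped at 0 and sorted by a stable descending sort (ties keep
decomposition order); each eigenvector is flipped so its largest-magnitude
loading is positive, making outputs reproducible; zero-variance columns
raise by default or are dropped with `drop_constant` (the standardization
denominator is undefined for them — dead ReLU embedding channels make this
a routine case after extraction, so the pipeline enables dropping).  The
model is fit on training data only; test data is standardized with the
training means/deviations before projection.  The eigenvalue-weighted
comprehensive score Σγ_iF_i/Σγ_i is computed and exposed as a per-segment
summary index but is not a pipeline stage.

## Modified Random Forest

Trees split on the (feature, threshold) pair maximizing the weighted-child
average of the node margin score

    elf(R) = Σ_k f_k (f_k − 1/C) = Σ_k f_k² − 1/C,

with f_k the node's class frequencies and C the number of classes — zero
for a uniform node, 1 − 1/C for a pure one.  Algebraically this is the
negated Gini impurity minus a constant, so the greedy optimum is well
defined; an expert knob (`n_margin_classes`) substitutes another constant
divisor, which cannot change which split wins.  Thresholds are midpoints
of consecutive distinct values; ties break to the lowest feature index,
then the lowest threshold; a node stays a leaf when no split strictly
improves its score.  Each tree is grown to purity (or the depth/leaf-size
limits) on a bootstrap of size n; prediction averages leaf frequency
vectors across trees, with argmax ties going to the lowest class index.

**Instance weighting.**  After the initial forest, each weighting round
(default 1) recomputes per-row weights proportional to the row's
out-of-bag cross-entropy −log p̂(true class) (probability floored at
1e-12; rows never out-of-bag get the uniform-prediction loss ln C),
normalizes them to sum n, and regrows the forest.  The weights act inside
the trees — in the weighted class frequencies of the split score and the
leaf vectors — while bootstrap sampling stays uniform.  This choice is
deliberate: sampling rows in proportion to loss starves trees of the easy
majority of the data and measurably inflates out-of-bag loss (mean +0.21
at the default generator scale), while criterion-level weighting leaves
coverage intact and is loss-neutral to mildly loss-reducing in the same
experiment.  Out-of-bag rather than in-bag predictions are used so badly
overfit rows cannot hide their own difficulty.

**Semi-supervised refinement.**  `ssl_refine` anneals: at each temperature
τ of a strictly decreasing schedule, pseudo-labels for unlabeled rows are
sampled from the forest's predictive distribution sharpened as p^{1/τ}
(τ < 1e-8 means hard argmax), and the forest is refit on labeled plus
pseudo-labeled rows.  The default schedule is geometric, 0.5 · 0.5^k for
three rounds.  Starting below τ=1 matters: at τ=1 the sampler reproduces
the raw predictive distribution and injects the forest's full error rate
as label noise (measured −0.027 mean test-accuracy change at 10% labels),
whereas starting at 0.5 squares the probabilities first (measured 0.000).

## Baselines

All three are written from first principles with fully specified
tie-breaking, and each is checked exactly against a brute-force oracle.
Naive Bayes uses Gaussian per-class per-feature likelihoods in the log
domain (the density product underflows double precision at large p), with
standard deviations floored at 1e-9 + 1e-6·(global feature sd).  The
decision tree splits on maximal information gain over midpoint thresholds;
zero-gain splits of impure nodes are accepted (the XOR pattern has no
positive-gain first split yet is separable two levels down), so growth
stops on purity, depth, leaf size, or absence of any valid threshold.
KNN is Euclidean majority vote with distance ties broken by training-row
index and vote ties by lowest class index; k defaults to 5.  The printed
pseudo-code conventions these algorithms are sometimes given in assume
binary features or two-class thresholds; the standard continuous-feature
forms are implemented instead.

## Evaluation

Confusion matrices have true classes as rows in the fixed
(negative, neutral, positive) order.  Accuracy is diagonal over total;
per-class precision TP/(TP+FP) and recall TP/(TP+FN) are one-vs-rest; the
F-measure is the harmonic mean; zero denominators yield 0 with a logged
warning.  The single summary row reported for the 3-class problem is the
macro (unweighted) average, with micro-averaging available — for
single-label multiclass data micro precision/recall both equal accuracy.

## Problem sizes and determinism

Recovery experiments run at the generator defaults (600 segments, 64
features); oracle-equivalence checks use 10–50 random instances of up to
200×16; the reweighting diagnostic averages 10 seeds at 180×16 with
30-tree forests.  Every stochastic stage draws its seed from one root seed
through fixed per-stage substreams, so a run is fully determined by its
inputs and configuration; repeated runs are byte-identical.

## Known limitations

The extractor is desk-scale: pure-numpy training is single-threaded and
unsuited to datasets beyond a few thousand segments or very deep stacks.
The generator's Gaussian block model cannot certify performance on real
recordings.  The margin score's linking function is taken as the identity
(the simplest choice that makes the score a proper purity measure); other
monotone choices would reweight margins differently.  The comprehensive
PCA score is exposed but unused downstream.  Forest growth is exact
(no histogram binning), so very large n per node costs O(n log n) per
candidate feature.
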