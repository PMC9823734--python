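# eegemotion

Classification of emotional state — negative, neutral or positive — from
EEG recording segments that have already been summarized into statistical
feature tables, the CSV format consumer headbands such as the Muse
(electrodes TP9/AF7/AF8/TP10) export.  The package is aimed at affective-
computing practitioners who want a fully seeded, fully tested
re-implementation of this pipeline on tabular EEG features, plus a
synthetic-data generator that makes every stage testable without any
dataset download.

The pipeline runs four stages:

1. **Min-max scaling** of each feature to the training range.
2. **Attention-residual CNN feature extraction**: dense 1-D convolutional
   blocks followed by an attention block whose soft mask N ∈ (0,1)
   combines with the trunk features OF by attention-residual learning,
   AM = (1 + N) ⊙ OF — a zero mask passes features through unchanged, so
   attention modules stack safely.  The pooled penultimate activations
   are the extracted features.
3. **Correlation-matrix PCA**: standardize, K = GᵀG/(n−1),
   eigendecompose, keep the smallest m components whose cumulative
   variance contribution CC_m = Σ_{i≤m} γ_i/Σγ reaches 85%.
4. **Modified Random Forest**: randomized trees whose splits maximize the
   margin-based node score elf(R) = Σ_k f_k(f_k − 1/C) = Σ_k f_k² − 1/C,
   with an instance-reweighting round driven by out-of-bag cross-entropy
   and an optional deterministic-annealing semi-supervised refinement.
   Gaussian Naive Bayes, an information-gain decision tree and k-NN are
   included as from-scratch baselines, and the evaluation suite reports
   confusion matrices with accuracy / precision / recall / F-measure
   (macro-averaged over the three classes).

See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a separable synthetic dataset (three balanced classes, 64
block-correlated features, class mean shifts of 6 within-class standard
deviations) and run the full pipeline:

```sh
$ eegemotion simulate --n-per-class 200 --p 64 --separability 6 --seed 1 --out demo.csv
wrote 600 rows x 64 features to demo.csv
$ eegemotion run --data demo.csv --classifier mrf --seed 1 --outdir runs
mrf: accuracy=0.9917 precision=0.9919 recall=0.9917 f_measure=0.9917
```

The run writes `runs/mrf_metrics.csv`, a confusion matrix and a JSON log
of all effective parameters.  The confusion matrix for this run:

```
,negative,neutral,positive
negative,39,0,1
neutral,0,40,0
positive,0,0,40
```

119 of the 120 held-out segments (20% of 600, stratified) are classified
correctly: the pipeline recovers the planted class structure almost
perfectly, as it should on linearly separable data — a nearest-centroid
rule already achieves ≥0.99 here, and the pipeline must not lose that.
With `--separability 0` the classes are identically distributed and the
same command lands in the 3-class chance band (accuracy ≈ 1/3), which is
the honesty check: no stage is allowed to manufacture signal.
`eegemotion compare` runs mrf, nb, dt and knn on one split and writes a
single comparison table; `--no-extractor` / `--no-pca` ablate individual
stages.

Library use mirrors the CLI:

```python
from eegemotion import GeneratorConfig, PipelineConfig, generate_dataset, run_pipeline

table = generate_dataset(GeneratorConfig(separability=6.0, seed=1))
result = run_pipeline(table, PipelineConfig(seed=1))
print(result.report.accuracy)        # 0.9917 (same split, same seed)
```

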