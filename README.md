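# melcbp

Micro-expression recognition from frame sequences with **Enhanced Local
Cube Binary Patterns**, multi-region joint sparse learning, and a
multi-kernel SVM under leave-one-subject-out (LOSO) evaluation.

Micro-expressions are involuntary facial movements lasting a fraction of
a second at very low intensity; recognizing them requires descriptors
sensitive to subtle, localized spatiotemporal change and an evaluation
protocol that measures generalization to unseen people. This package is
for researchers who want a tested, reproducible implementation of that
chain — including a synthetic clip generator so every stage can be
exercised without access to license-restricted face datasets.

## Method

Every pixel of a clip is encoded through its 3×3×3 cube (the 3×3
neighborhood at frames t−Δt, t, t+Δt), producing three complementary
binary code streams:

* **Spatial Difference LCBP** — for each temporal center c_i of the cube,
  an 8-bit sign code Σₙ s(xₙ − c_i)·2ⁿ⁻¹ against the eight neighbors xₙ
  of the last frame; spatial texture plus inter-frame center drift.
* **Temporal Direction LCBP** — eight zero-sum compass masks a₁..a₈ are
  correlated with four temporal planes P₁..P₄ cut through the cube; the
  code 8·argmaxᵢ Dᵢ(Pⱼ) + argminᵢ Dᵢ(Pⱼ) ∈ [0, 63] summarizes dominant
  and weakest motion direction per plane.
* **Temporal Gradient LCBP** — the 2-bit sign pattern of the two
  inter-frame gradients of a center-surround response S (brightening /
  darkening / pulse patterns).

Codes are histogrammed per grid cell (768 spatial + 260 temporal values
per cell). Feature selection fits, per grid i with design X_i and one-hot
labels Y,

    min_W Σᵢ ‖XᵢWᵢ − Y‖²_F + θ₁‖W‖²_F + δ Σ_{u<v} (‖m_u − m_v‖² + ε)⁻¹
          + θ₂‖W‖₂,₁

via accelerated proximal gradient (row-wise shrinkage, FISTA momentum
φ_k = 2/(k+2), backtracking line search, monotone safeguard). The ℓ₂,₁
penalty selects shared feature rows; the interclass term pushes class
centers m_u apart. Spatial and temporal selections feed two linear
kernels combined as c₁K₁ + c₂K₂ (c_z tuned by inner CV on training
subjects) in a one-vs-one SVM. Reported metrics: subject-pooled accuracy
100·ΣTᵢ/ΣSᵢ and macro-F1.

## Worked example

```python
from melcbp import PipelineConfig, run_pipeline
from melcbp.synthetic import SynthParams, generate_dataset

dataset = generate_dataset(SynthParams(seed=1))   # 60 clips, 10 subjects, 3 classes
report = run_pipeline(dataset, PipelineConfig(seed=1))
print(f"accuracy {report.overall_accuracy:.2f}%  macro-F1 {report.macro_f1:.4f}")
print(report.confusion)
```

prints

```
accuracy 96.67%  macro-F1 0.9666
[[18  0  2]
 [ 0 20  0]
 [ 0  0 20]]
```

96.67% of the 60 held-out clips (pooled over the 10 LOSO folds, each
testing one unseen subject) are classified correctly; the confusion
matrix rows are the true classes (brighten, darken, pulse) — two
brightening clips were mistaken for pulses, everything else is exact.
The same pipeline run on permutation-shuffled labels drops to chance
(~20–33%), confirming the score reflects class structure rather than
leakage.

The same pipeline is scriptable from the shell:

```sh
melcbp synth --out data/ --seed 1
melcbp extract data/manifest.csv --out features.tsv
melcbp train-eval data/manifest.csv --out report.json
```

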