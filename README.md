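# nucgrade

Explainable machine-learning grading of **nuclear cataract (NC)** severity
from anterior-segment OCT (AS-OCT) images. The lens nucleus hardens and
brightens as a cataract progresses; on AS-OCT this shows up not so much in
the raw image as in the **intensity histogram of the segmented nucleus
region**. `nucgrade` implements the full histogram-radiomics pipeline:

1. **Histogram** — bin the masked nucleus pixels over a configurable
   intensity window (default 5–150, width 5: the near-zero background
   spike and the sparse bright tail are excluded), producing bin
   proportions `X_i` with left boundaries `L_i`, `i = 1..N`.
2. **Features** — a catalog of 27 named visual features: 23 histogram
   statistics on the discretized intensity (mean `μ = Σ i·X_i`, variance,
   skewness, excess kurtosis, median, mean/median/robust absolute
   deviations, coefficient of variation, entropy `−Σ X_i log₂ X_i`,
   uniformity `Σ X_i²`, percentiles, mode, occupied-bin minimum / maximum /
   interquartile / range / quartile dispersion, and forward-difference
   gradient extrema with their locations) plus 4 clinical intensity
   statistics (mean, median, population SD, maximum of the raw masked
   pixels).
3. **Importance & selection** — *retraining* Shapley values: for feature
   `i`, `φ_i = Σ_{S⊆T\{i}} |S|!(|T|−|S|−1)!/|T|! · [f_{S∪{i}} − f_S]`,
   where every `f_S` is the classifier retrained on feature subset `S`
   (exact subset enumeration up to 12 features, seeded permutation
   sampling with antithetic pairs beyond), together with Pearson
   correlations feature-vs-grade and feature-vs-feature. A selection rule
   (Shapley floor + redundant-pair resolution) prunes the catalog; on the
   shipped clinical importance table it retains 22 of 27 features.
4. **Classifier (EMRR)** — an ensemble of one-vs-all ridge regressions,
   one per grade: `ŵ_c = (XᵀX + λI)⁻¹XᵀY_c` on the intercept-augmented
   design, scores `y_c(x) = ω_cᵀx + ω_0` combined by softmax
   `P(y=c|x) = e^{y_c}/Σ_j e^{y_j}` and decided by argmax.
5. **Metrics** — per-class and macro ACC/PRE/SEN/SPE/F1 from one-vs-rest
   confusion counts, plus plain (micro) accuracy.
6. **Synthetic cohorts** — a seeded generator of AS-OCT-like images
   (elliptical nucleus, mixture of background spike + truncated-normal
   opacity + bright tail per grade) so the entire chain is testable
   without clinical data.

Intended users: researchers reproducing or extending histogram-based,
interpretable NC grading, and anyone needing a compact reference
implementation of retraining-Shapley feature selection over a closed-form
multi-class ridge ensemble.

## Worked example

```python
from nucgrade import (SimConfig, generate_feature_table,
                      load_clinical_importance, select_features,
                      clinical_selection_rule)
from nucgrade.pipeline import train_eval

table = generate_feature_table(SimConfig(n_per_class=100, seed=0))
print(table.features.shape)                      # (300, 27)

selected = select_features(load_clinical_importance(), clinical_selection_rule())
print(len(selected))                             # 22

res = train_eval(table, selected=selected, lam=1.0, split_seed=0)
print(round(res.accuracy, 4))                    # 1.0
print(res.metrics.per_class.round(3))
```

prints

```
(300, 27)
22
1.0
        ACC  PRE  SEN  SPE   F1
normal  1.0  1.0  1.0  1.0  1.0
mild    1.0  1.0  1.0  1.0  1.0
severe  1.0  1.0  1.0  1.0  1.0
```

The three default synthetic grades are well separated at the histogram
level by construction, so a held-out accuracy of 1.0 on 90 test images is
the expected outcome; collapsing the three class profiles onto one
mixture drives the same pipeline to chance (≈ 0.33). The first row's
features (`D-Mean 5.53`, `D-Entropy 2.75`, `I-Mean 21.1`, `I-STD 14.4`)
show a normal-grade nucleus: low mean discretized intensity with mass
concentrated in the first few bins.

The same pipeline is scriptable from the shell:

```bash
nucgrade simulate --out data/sim --n-per-class 50 --seed 0
nucgrade extract  --images data/sim --out data/features.csv
nucgrade analyze  --features data/features.csv --out data/analysis
nucgrade train-eval --features data/features.csv \
    --selected data/analysis/selected.json --out data/run
nucgrade ablate   --images data/sim --out data/ablation.csv
```

`ablate` re-runs extraction + evaluation under the four histogram
settings {range 0–255, 5–150} × {interval 10, 5} on a single shared
split.

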