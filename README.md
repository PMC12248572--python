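# mfoct — multifractal texture analysis of retinal OCT images

`mfoct` quantifies the structural heterogeneity of optical coherence
tomography (OCT) scans with 2D box-counting multifractal analysis and
benchmarks how well those descriptors separate early diabetic retinopathy
(DR) from healthy retinas.  It is aimed at researchers studying texture
biomarkers in retinal imaging who need a tested, reproducible pipeline:
image conditioning, multifractal feature extraction, and a stratified
cross-validated classifier comparison — plus a synthetic module that makes
every stage verifiable against closed-form ground truth without any
external image data.

## The model

For a binary image (the white pixels after preprocessing and Otsu
binarization), the plane is tiled with boxes of side ε and each non-empty
box receives the probability p_i(ε) — its share of the foreground pixels.
The generalized dimensions are the scaling exponents of the moment sums,

    D_q = 1/(q-1) · lim_{ε→0} log Σ_i p_i(ε)^q / log ε        (q ≠ 1)
    D_1 =          lim_{ε→0} Σ_i p_i(ε) log p_i(ε) / log ε

estimated by ordinary least squares of log Σ p^q against log ε over a
dyadic scale schedule.  Three named values are read off the curve: the
box-counting dimension D_B = D_0, the information dimension D_I = D_1 and
the correlation dimension D_C = D_2.  The mass exponents τ(q) = (q−1) D_q
are Legendre-transformed into the singularity spectrum

    α(q) = dτ/dq,        f(α) = q·α(q) − τ(q),

whose landmarks — α_min, α_max, α_center, f(α)_max, the width
Δα = α_max − α_min and the symmetric shift α_center − (α_min + α_max)/2 —
complete a nine-descriptor feature vector per image.  A wide, left-skewed
spectrum signals heterogeneous, disrupted texture; DR tissue shows wider
spectra and larger α_max than healthy tissue.

The evaluation stage runs eight classifiers (logistic regression, random
forest, decision tree, polynomial-kernel SVM, gradient boosting, XGBoost-
and LightGBM-backed boosted trees, and a 128/64 ReLU multi-layer
perceptron) under stratified 5-fold cross-validation with within-fold
z-scoring, and reports accuracy, precision, recall, specificity, F1, a
Student-t 95% CI of the accuracy and a one-sided p-value against chance.

## Worked example

Analyse a multiplicative-cascade mass map whose spectrum is known in
closed form:

```python
import mfoct

res = mfoct.MultifractalModel(mfoct.make_binomial_cascade(8, 0.7, seed=1)).fit()
print(res.summary())
```

```
Multifractal box-counting analysis
==================================
scales (px):        128, 64, 32, 16, 8, 4
q grid:             -5 .. 5 (step 0.25)
D_B (q=0):            2.0000   (fit R2 1.0000)
D_I (q=1):            1.7626   (fit R2 1.0000)
D_C (q=2):            1.5718   (fit R2 1.0000)
alpha_min:            1.0679
alpha_max:            3.4352
alpha_center:         2.2515
f(alpha)_max:         2.0000
spectrum width:       2.3673
symmetric shift:      0.0000
```

The fitted D_B, D_I, D_C match the closed form 2·log2(0.7^q + 0.3^q)/(1−q)
— 2.0000, 1.7626, 1.5718 — to the printed precision, and the estimated
width 2.3673 sits within 0.01 of the analytic α(−5) − α(5) = 2.3751.

Run a small synthetic two-class study (phantom generation → preprocessing
→ extraction → cross-validated classification):

```python
table = mfoct.phantom_feature_table(n_per_class=50, seed=0)
bench = mfoct.ClassifierBenchmark(table, models=["mlp", "random_forest"], seed=42).fit()
print(bench.summary())
```

```
Stratified 5-fold benchmark (100 rows, seed 42)
================================================================
mlp                  acc 0.9600 [0.9081, 1.0119]  prec 0.9618  rec 0.9600  spec 0.9600  F1 0.9599
random_forest        acc 0.9500 [0.9061, 0.9939]  prec 0.9436  rec 0.9600  spec 0.9400  F1 0.9504
```

Here the MLP separates the DR-like phantoms (wide spectra, mean Δα ≈ 1.2)
from the Normal phantoms (mean Δα ≈ 0.65) with 96% cross-validated
accuracy; the bracketed interval is the 95% CI of the accuracy across
folds.

The same workflow is available from the shell:

```sh
mfoct generate phantoms --n-per-class 100 --seed 42 --out-dir images/
mfoct preprocess --in-dir images/ --out-dir processed/
mfoct analyze --in-dir processed/ --out features.csv
mfoct evaluate --features features.csv --models all --k 5 --seed 42 --out-dir reports/
```

or end-to-end with `mfoct run --config cfg.yaml` (the resolved config and
seed are written next to the outputs).

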