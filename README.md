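# antiangio

Sequence-based prediction and characterization of anti-angiogenic peptides.

Anti-angiogenic peptides — short sequences (roughly 5–50 residues) that
inhibit new blood-vessel formation, typically by interfering with VEGF
signaling — are a promising route to anti-cancer therapeutics, but wet-lab
screening is slow. This package provides the standard machine-learning
pipeline for recognizing them from primary sequence alone, aimed at
computational biologists building peptide-bioactivity classifiers and at
peptide chemists who want interpretable composition-level read-outs of
what distinguishes active from inactive sequences.

## What it computes

**Feature encoders.** A peptide **P** of length *L* is mapped to a
fixed-length vector under five schemes:

- **AAC** — amino-acid composition, the 20 residue frequencies
  [aa₁, …, aa₂₀]ᵀ;
- **DPC** — dipeptide composition, the 400 overlapping-pair frequencies
  [dp₁, …, dp₄₀₀]ᵀ;
- **PCP** — physicochemical properties: one sequence-averaged value per
  AAindex scale (a small AAindex-format subset ships with the package;
  any AAindex1 flat file can be supplied);
- **PseAAC** — Chou-style pseudo amino acid composition: the 20
  frequencies plus λ sequence-order factors
  θ_k = (1/(L−k)) Σᵢ Θ(Rᵢ, Rᵢ₊ₖ), with Θ the mean squared difference over
  standardized hydrophobicity, hydrophilicity and side-chain-mass scales,
  jointly normalized by 1 + ϖ·Σθ so all 20+λ components sum to 1;
- **Am-PseAAC** — the amphiphilic variant, whose 2λ factors track
  hydrophobicity and hydrophilicity correlation products separately
  (dimension 20 + 2λ).

**Classifier.** A bagged-CART random forest; the prediction score is the
fraction of trees voting positive, tuned over ntree ∈ {100, …, 500} and
mtry ∈ {1, …, 10} by 5-fold cross-validation when requested.

**Evaluation protocol.** Repeated stratified 80/20 random splits (default
10 rounds); per round, pooled 5-fold CV on the training set plus an
independent test on the hold-out, reported as Ac / Sn / Sp / MCC / auROC,
mean ± SD across rounds.

**Interpretation.** Feature importance as the mean decrease of Gini index
(MDGI), averaged over ten forests grown at mtry = 2, 3, 5, 7, 9, 11, 13,
15, 17, 20 with 100 trees each; per-residue class composition contrasts
with Welch tests; positional residue-frequency matrices for the N- and
C-terminal regions (the numeric backbone of sequence logos).

**Synthetic data.** A generator that draws peptides i.i.d. from per-class
residue compositions — defaulting to the published class compositions of
anti-angiogenic vs. non-antiangiogenic benchmark peptides — so the whole
pipeline is exercisable without any external download.

## Worked example

```python
from antiangio import (GeneratorSpec, RFConfig, composition_diff,
                       feature_matrix, generate, mdgi_profile,
                       run_experiment, summary_table)

dataset = generate(GeneratorSpec(seed=7))          # 137 + 137 peptides
results = run_experiment(dataset, ["AAC"], rounds=10, seed=7,
                         config=RFConfig(ntree=100, seed=7))
print(summary_table(results).to_string(index=False))
```

```
feature_set            phase           Ac           Sn            Sp         MCC       auROC
        AAC        5-fold CV 79.36 ± 1.99 78.44 ± 3.04  80.28 ± 2.34 0.59 ± 0.04 0.87 ± 0.01
        AAC independent test 82.14 ± 4.29 80.00 ± 8.62 84.29 ± 10.41 0.65 ± 0.09 0.90 ± 0.04
```

The two classes differ only in residue composition, and a composition
encoder plus forest separates them with ~82% held-out accuracy averaged
over ten independent splits (MCC 0.65, auROC 0.90). The importance
profile and composition contrast explain *why*:

```python
X, y = feature_matrix(dataset, "AAC")
print(mdgi_profile(X, y, seed=7).top(5)[["mdgi", "rank"]])

table = composition_diff(dataset)
print(table.loc[["C", "S", "R"], ["mean_positive", "mean_negative",
                                  "difference", "p_value"]].round(4))
```

```
        mdgi  rank
C  32.077043     1
S  19.799957     2
A  10.639553     3
E   7.268699     4
V   7.086351     5

         mean_positive  mean_negative  difference  p_value
residue
C               0.0477         0.0103      0.0374   0.0000
S               0.0963         0.0488      0.0475   0.0000
R               0.0816         0.0560      0.0256   0.0004
```

Cysteine tops the MDGI ranking and is almost five-fold enriched in the
positive class (4.8% vs 1.0% of residues, Welch p ≈ 0), with serine and
arginine close behind — the composition signature the generator plants
and the pipeline recovers.

The same pipeline is available from the shell:

```bash
antiangio simulate --seed 7 --outdir sim/
antiangio experiment --manifest sim/manifest.csv --features AAC \
    --rounds 10 --seed 7 --outdir exp/
antiangio train --manifest sim/manifest.csv --features AAC \
    --seed 7 --model-out model.joblib
antiangio predict --fasta query.fasta --model model.joblib \
    --features AAC --out predictions.csv
```

To work with real data instead, pass paired FASTA files
(`--positive`/`--negative`) or a CSV manifest with `id,sequence,label`
columns; `antiangio encode`, `cv` and `importance` cover the remaining
steps. See `docs/methods.md` for the model details, parameter defaults
and known limitations.

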