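# Methods

## The problem and the model

The task is binary classification of short peptides (≈5–50 residues) as
anti-angiogenic or not, from primary sequence alone, together with an
interpretable account of which sequence features carry the signal. The
model is deliberately classical: fixed-length sequence encodings feeding a
random forest. Forests handle the modest sample sizes typical of curated
bioactive-peptide sets (a few hundred sequences), need little tuning, and
expose an impurity-based importance measure that supports the
characterization half of the task.

The positive class is called `positive` (anti-angiogenic) throughout;
scores are the fraction of trees voting positive.

## Encoders

All encoders produce fixed-dimensional vectors with a frozen feature
order (residues alphabetical by one-letter code, dipeptides
lexicographic, AAindex entries in table order). Persisted models carry
their feature-name manifest and refuse to predict when it does not match.

**AAC** (20) and **DPC** (400) are occurrence frequencies; DPC counts the
L−1 overlapping windows, so both sum to exactly 1. DPC requires L ≥ 2.

**PCP** maps each AAindex entry to the sequence mean of its per-residue
values. By default each 20-value scale is z-scored over the alphabet
first (population SD), so scales on incommensurate units contribute
comparably; pass `standardize=False` for raw means. Whether to
standardize before averaging is genuinely open — both conventions appear
in the literature — hence the flag. The bundled table is a small AAindex1
subset (hydropathy, hydrophilicity, polarity, isoelectric point,
molecular weight, consensus hydrophobicity); the parser accepts any
AAindex1 flat file and drops entries containing `NA` at load.

**PseAAC** augments AAC with λ sequence-order correlation factors

    θ_k = 1/(L−k) · Σ_{i=1}^{L−k} Θ(R_i, R_{i+k}),
    Θ(a, b) = ⅓[(H₁(b)−H₁(a))² + (H₂(b)−H₂(a))² + (M(b)−M(a))²],

where H₁ (hydrophobicity, Eisenberg consensus), H₂ (hydrophilicity,
Hopp–Woods) and M (side-chain mass) are each standardized to zero mean /
unit SD over the 20 amino acids before use (population SD, the original
pseudo-composition convention). Components are

    p_u = f_u / (1 + ϖ·Σθ)        u ≤ 20,
    p_{20+k} = ϖ·θ_k / (1 + ϖ·Σθ),

with f the residue frequencies. The normalizer uses the unit term rather
than the floating-point sum of frequencies, which makes the ϖ = 0 (and
λ = 0) limit reproduce AAC bit-for-bit. Dimension is 20 + λ; λ must be
smaller than the sequence length.

**Am-PseAAC** replaces the squared-difference factors with 2λ interleaved
correlation *products*, τ_{2k−1} from H₁ and τ_{2k} from H₂, normalized
the same way (dimension 20 + 2λ). Because the products are signed, the
normalizer 1 + ϖ·Στ can be negative for short, strongly amphiphilic
sequences; components then leave [0, 1] although their sum is still 1.
Only an exactly vanishing normalizer is an error. The presets keep ϖ
small, which makes this rare.

Parameter presets (ϖ, λ) for the two dataset styles:

| preset      | PseAAC       | Am-PseAAC    | intended data            |
|-------------|--------------|--------------|--------------------------|
| `benchmark` | ϖ=0.9, λ=1   | ϖ=0.9, λ=1   | full-length peptides     |
| `nt15`      | ϖ=0.1, λ=2   | ϖ=0.2, λ=3   | first-15-residue (NT15)  |

`optimize_pse_params` re-derives such values on any labeled dataset by
grid search (ϖ ∈ {0, 0.1, …, 1}, λ ∈ {1, …, 10}) maximizing 5-fold CV
accuracy, skipping λ values not smaller than the shortest sequence; ties
prefer smaller λ, then smaller ϖ (cheaper, less order-sensitive models).

Nine registered combinations (the five single schemes plus
AAC+PseAAC, AAC+Am-PseAAC, PseAAC+Am-PseAAC, AAC+PseAAC+Am-PseAAC) cover
the standard comparison grid; `concat` prefixes names by scheme and can
drop repeated pure-AAC blocks. Concatenated dimension is logged, never
assumed: e.g. the `nt15` presets give 20 + 22 + 26 = 68 for the triple
combination.

## Dataset preparation

- **Cleaning**: sequences containing residues outside the 20-letter
  alphabet (X, U, B, Z, …) are dropped (or rejected, by flag); counts are
  logged. Input is case-insensitive; sequences are stored upper-case.
- **Redundancy filtering**: greedy longest-first representative
  selection; a sequence is discarded iff its ungapped identity (matching
  positions over the shorter length) with an already-kept representative
  strictly exceeds the threshold (default 0.90). This is a deliberate
  simple stand-in for full clustering programs: the filter is
  preprocessing, not the method, and the greedy rule is deterministic and
  order-stable.
- **NT15 truncation**: keep the first min(n, L) N-terminal residues
  (default n = 15); idempotent.
- **Splitting**: stratified repeated random splits. Per class,
  floor(fraction·n) sequences go to training (default fraction 0.8, ten
  rounds). Per-round seeds derive from the master seed by a fixed affine
  hash, so any round is reproducible in isolation. Train/test partitions
  are exact and disjoint by construction.

## Forest and evaluation

The forest is scikit-learn's `RandomForestClassifier` (bagged, fully
grown CART trees) behind this package's contracts: vote-fraction scores
(ntree·score is always an integer), calls positive iff score strictly
exceeds the 0.5 threshold (an exact tie is negative — majority voting),
and per-sample out-of-bag bookkeeping recovered from the per-tree
bootstrap streams (the OOB fraction concentrates near (1−1/N)^N ≈ 1/e,
the classical "about a third"). `mtry` defaults to floor(√M).

Metrics: Ac, Sn, Sp, MCC with MCC defined as 0 whenever a denominator
factor vanishes; Sn/Sp are 0 on an empty denominator. The ROC is a
descending threshold sweep over distinct scores with equal scores
grouped (ties move diagonally; an all-ties score set scores exactly 0.5)
and trapezoidal area; the test suite cross-checks it against the
Mann–Whitney rank formulation. AUC convention is standard: 1 = perfect,
0.5 = random.

Cross-validation pools all out-of-fold predictions into a single
confusion table and ROC before computing metrics — one number per metric
per CV run, invariant to fold order for a deterministic learner; k = n is
the jackknife. Per-fold-averaged metrics would differ only in higher
variance; pooling was chosen because single-round protocol reports are
single numbers.

Hyper-parameter tuning searches ntree ∈ {100, …, 500} × mtry ∈ {1, …, 10}
by mean 5-fold CV accuracy, skipping mtry values above the feature count;
ties prefer smaller ntree then smaller mtry. Whether to re-tune per split
round is a flag (`tune_per_round`, default off — a fixed modest forest is
cheaper and the accuracy surface is flat in practice).

Experiment reports aggregate per-round metrics as mean ± sample SD
(SD = 0 for a single round), percentages printed to two decimals.

## Importance and compositional analyses

**MDGI.** A node's Gini impurity is 1 − Σ_c p²(c|t). A feature's
importance in one forest is the total impurity decrease over all splits
on that feature, weighted by the samples reaching each split and averaged
over trees; values are rescaled by the training-set size to the scale of
the classical R implementation (so they are comparable across forests of
equal n, and top features on a ~270-sample composition task land in the
~10–30 range). The profile averages ten forests grown at
mtry ∈ {2, 3, 5, 7, 9, 11, 13, 15, 17, 20}, ntree = 100, each with a
deterministic derived seed; schedule entries above the feature count are
clamped with a warning. Ranks break ties by feature order. Impurity
importances depend on the RNG stream, so reordering input columns
perturbs values slightly; the averaging keeps the ranking stable (tested
via rank agreement, not bitwise equality).

**Composition contrast.** Per-peptide residue fractions are averaged per
class; the difference (positive minus negative, summing to 0 across the
alphabet) is ranked by absolute value. Significance uses Welch's unequal
variance two-sample test on the per-peptide fractions — the appropriate
default when class variances differ and no test is otherwise mandated;
Student's pooled variant is selectable and the test identifier is
recorded in the output.

**Positional matrices.** 15×20 per-class residue-frequency matrices for
each terminus: N-terminal matrices left-aligned, C-terminal
right-aligned; a sequence shorter than 15 contributes only to positions
it reaches and each occupied position normalizes by its effective count.
The matrices are written as CSV for any logo-rendering tool; graphics are
out of scope. Dipeptide importance reshapes to a 20×20 matrix the same
way.

## Synthetic generator

`GeneratorSpec` defaults encode the benchmark study conditions: 137
peptides per class, lengths uniform on [5, 50], residues drawn i.i.d.
from the published class-mean compositions of anti-angiogenic
(Cys 0.047, Ser 0.096, Arg 0.088, …) versus non-antiangiogenic
(Cys 0.014, Leu 0.095, Ala 0.086, …) peptides, renormalized to exact
simplexes. `plant_signal` shifts one residue's probability by +δ in
positives and −δ in negatives with proportional renormalization of the
rest, erroring on infeasible shifts; it is the input for
importance-recovery experiments (a planted Cys contrast is recovered at
rank 1 by the MDGI protocol in ≥9/10 seeded replicates).

What the generator does *not* emulate: positional or motif structure,
length–class dependence, residue autocorrelation, and the redundancy
structure of patent-derived data. Passing tests therefore demonstrate
that the pipeline recovers composition-level signal under controlled
conditions — not that it attains any particular accuracy on real curated
peptides, whose signal is richer (real benchmarks reward the
order-sensitive encoders more than i.i.d. draws can).

## Numerical choices and problem sizes

- Standardization uses population SD (ddof = 0) over the 20 residues.
- Tie-breaks: tuning prefers cheaper configurations; importance ranks by
  feature order; a vote exactly at threshold is a negative call.
- Determinism: every stochastic step (splits, folds, forests, generator)
  takes an explicit or derived seed; identical seeds give identical
  outputs, including FASTA bytes from the generator.
- Test and reproduction runs use the study-scale conditions (137+137
  peptides, 10 rounds, ntree = 100; 10 importance replicates), which
  complete in well under a minute each on one CPU.

## Known limitations

- The redundancy filter is a greedy anchored-identity rule, not a full
  local-alignment clustering; for heavily redundant real data a dedicated
  clustering tool is preferable upstream.
- Out-of-bag bookkeeping reconstructs bootstrap indices from
  scikit-learn's internal sampling helpers, which are not public API; the
  test suite pins the behavior.
- PCP breadth is limited by the bundled AAindex subset; supply a full
  AAindex1 file for the complete property space.
- MDGI, like all impurity importances, is biased toward features with
  many split points and does not imply causality; the composition
  contrast table is the complementary, model-free view.
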