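# Methods

## The problem

Aqueous solubility — reported here as log Sw, the base-10 logarithm of the
molar solubility (mol/L) of a neutral organic compound in water — spans more
than thirteen orders of magnitude across environmentally and pharmaceutically
relevant chemistry, and experimental determinations themselves carry an
expected spread of roughly 0.5–0.6 log units.  `solugraph` implements a
complete modelling pipeline for this property: dataset curation, training-set
augmentation, a graph-convolutional regressor, a fivefold consensus with an
uncertainty proxy, a structure/reliability applicability domain, and the
evaluation statistics used to judge all of it.

## Curation model

Raw solubility tables are noisy: one structure appears under several
identifiers, with several measured values, alongside salts, mixtures and
inorganics that a neutral-organic model cannot represent.  The pipeline:

1. standardizes every SMILES to a canonical form and full InChIKey;
2. merges rows by full InChIKey (tautomers are deliberately *not* merged at
   this stage — they are exploited later as augmentation);
3. resolves multiple measurements per structure: a single value is kept as
   is; exactly two conflicting values are arbitrated by an independent
   reference prediction (nearest wins; the tie goes to the more negative,
   less soluble value); three or more values resolve to the value nearest
   their mean.  With no reference model available the two-value case is a
   hard error by default (`two_value_fallback="mean"` opts into the
   nearest-to-mean rule instead);
4. applies eligibility filters with *strict* cutoffs: multi-fragment
   structures (salts/mixtures; no desalting is attempted), carbon-free
   structures (the operational definition of "inorganic"), molar mass
   > 900 g/mol, and log Sw > 0.50 (treated as fully miscible);
5. optionally flags records whose label deviates from a model prediction by
   more than 1 log unit.  Flagging is advisory — mirroring a manual-review
   step — and can be iterated (default 3 passes); records are never removed
   automatically.

The curation log accounts for every input row exactly once
(`n_input = n_output + Σ removals`), with rows merged into a surviving
record counted under `merged_duplicate` and multi-reason filter failures
counted once (first reason in the order multi-fragment, inorganic,
too-large, miscible) with the full histogram kept separately.

## Augmentation

Each *training* chemical is expanded into deduplicated SMILES spellings —
canonical/aromatic, InChI-ordered ("universal"), InChI-round-tripped
("inchified"), kekulized, all-hydrogens-explicit, and dative-bond rewrites of
charge-separated motifs — plus rule-based tautomers.  All variants carry the
parent's label.  Two validation gates keep augmentation honest: non-tautomer
variants must re-parse to the parent's *full* InChIKey, and tautomers must
conserve the molecular formula, heavy-atom count and the 14-character
InChIKey skeleton.  Variants failing a gate are dropped and logged.  Note
that carbon-bound keto–enol tautomers change the standard InChI skeleton and
are therefore excluded by the second gate; the tautomers that survive are
the heteroatom-mobile ones the skeleton ignores.

Tautomer-rich chemicals are capped at 50 tautomers per parent by a uniform
random draw, seeded per parent (derived from the run seed and the parent
InChIKey), so augmentation is reproducible molecule by molecule.  The raw
enumerator is bounded (512 candidates, 2048 transforms) for runtime.
Validation and test sets are never augmented; every evaluation uses each
parent's canonical structure only.

## Featurization

Molecules become heavy-atom graphs: hydrogens are implicit (counted in an
attached-H block), bonds are untyped edges, aromaticity lives on atoms.  The
44-wide node feature vector concatenates one-hot blocks for atom symbol
(C, N, O, S, F, Cl, Br, I, P, B, Si, Se + other), degree (0–6), implicit
valence (0–6), hybridization (s…sp3d2) and attached hydrogens (0–4), plus
scalars for formal charge and radical electrons, an aromaticity flag and
R/S/unspecified chirality flags.  One-hot overflows saturate at the last
bucket.  The feature specification is serialized into every model file so
prediction always featurizes exactly as training did.

## Network and training

Two graph-convolution blocks (64 then 128 units), each computing the
neighbor-sum message `m_i = h_i + Σ_{j∈N(i)} h_j`, an affine map, batch
normalization, a leaky rectifier (negative slope 0.1) and a self-plus-
neighbors element-wise max pool; then a per-node dense layer (128) with
batch normalization and activation; a sum readout over each molecule's
nodes; and a linear head.  Training minimizes mean absolute error with Adam
at learning rate 5e-4, dropout 0.1 after each pooled/dense block, batch
size 64, for exactly 130 epochs.

Numerical choices worth knowing:

* **Labels are standardized internally** (mean/SD of the training labels);
  the statistics are stored in the model and predictions are returned in
  log units.
* **The output head is zero-initialized**, so the untrained network predicts
  the training-label mean; this stabilizes the short 130-epoch schedule.
  All other weights use fan-in-scaled uniform initialization.
* **Batch normalization** uses batch statistics (biased variance) in
  training and running statistics (momentum 0.9) at inference.
* **Max-pool gradients** flow to the first candidate attaining the maximum
  (the node itself first, then neighbors in index order) — the conventional
  deterministic subgradient.
* Forward, backpropagation and Adam are implemented directly on NumPy
  arrays (sparse adjacency for neighbor sums; two numba kernels fuse the
  batch-norm/activation passes and the pool backward, with equivalent pure
  NumPy fallbacks).  Training is exactly reproducible for a seed on one
  worker; all randomness (init, shuffling, dropout) flows from one
  generator.
* Per-epoch validation rmse is computed on unaugmented parent structures in
  inference mode, so the training history is directly comparable to
  held-out fold statistics.

## Splits and consensus

10% of chemicals (rounded) are split off once as a shared test set.  The
remainder is distributed five times into 70%/20% train/validation sets; a
seeded round-robin pass guarantees every non-test chemical validates at
least once, and a post-hoc label-histogram report per subset serves as the
homogeneity check (no constrained stratification is attempted).  One model
is trained per fold on that fold's augmented training parents.

The consensus prediction is the arithmetic mean of the five member outputs;
their **population** standard deviation (divisor 5, recorded in the output
metadata) is the reliability proxy, banded half-open:
0 ≤ SD ≤ 0.1 high, 0.1 < SD ≤ 0.3 good, 0.3 < SD ≤ 0.5 moderate,
SD > 0.5 low.

## Applicability domain

Circular fingerprints (radius 2, 2048 bits — the field default, serialized
with the model) define Tanimoto distances.  For each training compound the
mean distance to its k = 12 nearest neighbors is computed (ties broken by
training index); the global reference value is the upper outlier fence
Q3 + 1.5·IQR of those means; each compound's base radius is its mean
distance to all neighbors within the reference value (compounds with none
are isolated, radius 0).  Radii are then shrunk by prediction reliability:
`f = 1/(1 + w·(rel_sd + rel_dev))` with `rel_sd` the consensus SD over
|consensus mean| (denominator floored at 1e-6) and `rel_dev` the absolute
deviation from experiment over the training-label spread (max − min),
w = 1.  This functional form is this package's own concretization of
"correct the radii by prediction reliability": it equals 1 when both inputs
vanish and decreases monotonically in each, and it is recorded, with w, in
the saved domain model.  A query is inside the domain iff at least one
training compound's corrected radius covers it.

## Evaluation statistics

With errors `e_i = pred_i − exp_i` (positive bias = overprediction):
rmse, bias, most negative/positive single error, squared Pearson r², the
predictive q² `1 − Σe²/Σ(exp − ȳ_ref)²` using the *training* mean as
reference when available (the evaluation-set fallback is flagged in the
report), and signed 95th percentiles of the negative and positive error
subsets (linear-interpolation percentiles).  `rmse² = bias² + Var(e)`
(population variance) holds as an exact identity and is tested to 1e-12.
Subset views slice by non-hydrogen-atom bins
(≤10, 11–15, 16–20, 21–25, 26–30, >30) and by an ionizability predicate
over a documented SMARTS list (carboxylic/sulfonic/phosphonic acids,
phenols, thiols, sulfonamide/imide N–H, non-amide amines,
amidines/guanidines).

## Synthetic data: what it emulates and what it does not

The generator assembles single-fragment organics from a small grammar
(alkyl chains up to 10 carbons, up to two benzene rings, hydroxyl / amine /
carboxyl / halogen decorations) and labels them with an additive
group-contribution law,

    log Sw = 0.7 − 0.55·(aliphatic C) − 0.35·(aromatic C)
                 + 0.45·(OH) + 0.30·(amine N) + ε,  ε ~ N(0, 0.4²),

clipped at the 0.50 miscibility cutoff.  The coefficients place grammar-
sized molecules in roughly [−13, 0.5], reproducing the monotone
size–solubility trend and the sign of the hydrogen-bonding corrections; the
0.4 log-unit noise slightly tightens the 0.5–0.6 spread expected of
experimental values so that recovery bounds stay crisp.  Labels are an
exact function of structure plus independent noise, which is what makes
parameter-recovery statements testable: a model cannot beat the noise floor
without leaking structure across splits.

What the generator does **not** emulate: melting-point/crystal-packing
physics, pH-dependent (apparent) solubility, tautomer-sensitive labels,
stereochemistry, and the heteroscedastic difficulty of real assays.
Passing the pipeline's recovery tests therefore demonstrates that the
machinery — curation, augmentation, training, consensus, domain — works as
specified on data of realistic shape; it does not certify accuracy on real
measurements.  One visible consequence: on synthetic data the consensus SD
ranks error bands only weakly, because the dominant error source
(homoscedastic label noise) is invisible to an ensemble-spread uncertainty
proxy.

## Problem sizes used by the test suite and acceptance script

The study-scale checks run on the generator's default conditions — 1000
chemicals, noise SD 0.4, fixed-test fivefold 70/20/10 splits, full
augmentation, the reference network (64/128, lr 5e-4, dropout 0.1, L1,
130 epochs) — with three independent seeds where a stochastic property is
asserted by majority.  Unit tests exercise the same code paths on smaller
datasets (40–120 chemicals) and narrower layers, which changes capacity but
no contract.  The end-to-end CLI reproducibility check runs the full
default pipeline on 150 chemicals.

## Known limitations

* Two-value conflicts genuinely need a reference model; the iterative
  workflow (train, screen outliers, re-resolve, repeat) is supported but
  not automated end to end.
* "Reactive chemicals and polymers" have no structural detection rule; an
  exclusion list and a manual-review annotation file stand in.
* The AD correction factor is a monotone concretization, not a literature-
  exact formula; coverage numbers depend on it only through the radii.
* Edge features (bond types) are deliberately absent; aromaticity is
  carried on atoms.
* The GCN is CPU-bound NumPy; it is sized for datasets of order 10⁴
  chemicals, not 10⁶.
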