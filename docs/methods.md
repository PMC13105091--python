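# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic benchmarks do and do not establish.

## Problem setting

The prediction target is odorant–receptor affinity: given a small volatile
molecule (a SMILES string) and an olfactory receptor (an amino-acid
sequence), predict either a continuous response (spike-rate style
electrophysiology panels, regression mode) or a binary responsive /
non-responsive label (screening compilations, classification mode).  Datasets
are represented as an `InteractionDataset`: odorants, receptors, and a list
of (odorant, receptor, value) interactions with optional per-record weights
and quality tiers.  All joins are keyed on string IDs, never row position.

## Normalization

Continuous responses are z-scored **globally**: one mean and one population
(ddof = 0) standard deviation computed over all interactions pooled, never
per receptor.  Per-receptor scaling would erase genuine between-receptor
gain differences, which are part of the signal.  The transform is idempotent
to 1e-10 and refuses constant response vectors (σ = 0).

Leakage caveat: `zscore_global` scales the whole dataset at once.  For
strictly leakage-free protocols, fit the scaling on training folds only and
apply it to test folds; the whole-dataset variant exists because panel-style
studies commonly normalize once before any split, and reproducing that
convention must be possible.  The benchmark and experiment drivers accept
either a pre-scaled or raw dataset, so both protocols are available.

## Representations

Featurizers are pure functions `records -> matrix` behind a registry keyed
by name.  The self-contained ones used by the test suite:

* `reference_counts` — character counts of the SMILES string over a fixed
  19-symbol alphabet.  Deliberately simple: the synthetic generator plants
  its signal in these counts, so any competent token encoder can in
  principle recover it.
* `random` — the lower-bound baseline: an i.i.d. standard-normal vector per
  molecule.  The stream is keyed to (seed, SMILES), not to the row, so the
  same molecule receives the same vector in every fold and dataset.  Keying
  to rows would make the molecule+protein benchmark's behaviour on the
  random representation impossible to reproduce, because train and test
  copies of a molecule would decorrelate.
* `kmer` (proteins) — length-normalized k-mer composition (default k = 1).
  It stands where a frozen protein-embedding model would attach at full
  scale; both are fixed, deterministic per-receptor vectors, which is the
  only property the pipeline relies on.
* `ecfp` — Morgan fingerprints (radius 2, 256 bits) via RDKit, registered
  only when RDKit imports; a real-chemistry backend behind the same
  interface.

Pooling of token-level embeddings into fixed vectors defaults to a masked
mean over non-padding tokens; a first-token mode is provided, since both
conventions are common for transformer encoders.

The **neural representation** of an odorant is the vector of responses it
elicits across the receptor panel (n_odorants × n_receptors matrix, columns
in receptor declaration order).  It requires a full-factorial regression
panel; missing cells either raise or are zero-filled, by explicit policy.

## Shape metrics

Two angular dissimilarities between representations of a common item set,
both preceded by row alignment to a common item order, column centering, and
zero-padding of the narrower matrix to a common width (padding adds empty
dimensions, which neither metric sees):

* **Orthogonal Procrustes distance** `arccos(||X'Y||_*)` on unit-Frobenius
  matrices, where `||.||_*` is the nuclear norm of the cross-product.
  Invariant to orthogonal transforms and isotropic scaling; sensitive to
  anisotropic stretching.
* **CCA distance** `arccos(Σρ_i / sqrt(k_x k_y))` where ρ_i are canonical
  correlations of the whitened matrices and k are the retained ranks
  (relative eigenvalue cutoff `rank_tol`, default 1e-9).  Invariant to any
  invertible linear map of either input.

The angular form makes self-distance exactly 0 and bounds values in
[0, π/2]; correlations and nuclear norms are clipped to [0, 1] before
`arccos` to guard floating-point overshoot.  Because published distances of
this family do not always state their normalization (angular vs chordal),
cross-study numerical comparisons should be qualitative: orderings and block
structure, not absolute values.

A caution on sample size: with n items, whitening retains up to n − 1
dimensions, so representations whose width approaches n produce
canonical correlations near 1 by overfitting.  Shape analyses here keep
item count comfortably above the retained ranks.

## Ridge benchmarks (MO / MP)

* **MO** (molecule only): one ridge model per receptor on odorant features
  alone; the fold score is the *unweighted* mean of per-receptor test R², so
  every receptor counts equally.  A receptor with constant training response
  predicts that constant and is flagged.
* **MP** (molecule + protein): a single ridge on the concatenation
  [chem ‖ protein] over all interactions, scored on the pooled test fold.

Ridge is solved in closed form on internally standardized features (mean 0,
population SD 1; constant columns receive a unit-scale guard and hence a
zero coefficient) with an unpenalized intercept.  λ is selected per fit by
inner 3-fold cross-validation over a log-spaced grid, default 10⁻³…10³ in 13
points, ties resolved toward the smaller λ.  At λ = 0 the standardized
design must be full column rank, and the fit matches an independent
normal-equations OLS oracle to 1e-8.

R² is 1 − SSres/SStot with SStot about the **test-set** mean.  This is the
standard convention and the one under which the naive train-mean predictor
scores exactly 0 only when train and test means coincide — negative scores
for weak models depend on it.

## The two-stage affinity model

**Stage 1 — LoRA-adapted multi-modal transformer.**  A chemical token
encoder (SMILES characters) and a protein token encoder (amino acids) are
projected to a shared model dimension and fused by bidirectional
cross-attention; a learned `<cls>` token reads the fused sequence out
through attention and a linear head maps it to the prediction.  The package
ships tiny frozen encoders (2 self-attention layers, character vocabulary,
dimension 32) whose weights are random: they stand at the architectural
position of pre-trained foundation models, and the encoder interface is the
attachment point for real ones.  Claims about the *benefit of pre-training*
therefore cannot be made from this package's experiments; claims about the
*mechanics of adaptation* can.

LoRA adapters wrap the query and value projections of the chemical encoder
(optionally also the protein encoder): `y = Wx + (α/r)·B(Ax)` with A drawn
from a child random stream at SD 1/√d_in, B zero-initialized, and W frozen.
Defaults r = 4, α = r (unit effective scale), dropout 0.  Zero-initialized B
makes the adapted forward pass bit-identical to the frozen model, which is
asserted, and disabling adapters recovers the frozen-representation
comparator exactly — the two model variants share identical base weights by
construction because adapters are always built and only gated.

Training: Adam on MSE (regression) or weighted binary cross-entropy on
probabilities (classification), batch size 64, learning rate 3e-3, gradient
flow restricted to the trainable scope (adapters per scope, plus fusion,
projections, `<cls>` and head; encoder base weights never receive updates).
The validation metric (R² or MCC) is logged per epoch; the best checkpoint
is restored at return, and the best value is reported as the standalone
transformer score.  On the planted panels the validation trace shows an
initial plateau of seed-dependent length (roughly 4–12 epochs) before the
cross-attention head locks onto the signal, so scripted runs budget ~20
epochs rather than stopping at the first flat stretch.

**Stage 2 — gradient-boosted ensemble.**  With the transformer frozen,
three XGBoost models are trained on (1) the `<cls>` features, (2) the
concatenated original chemical and protein representations, (3) both
concatenated; identical hyperparameters and seed, per-record weights
honored.  The final prediction is a weighted sum (of probabilities in
classification mode) with weights on the 2-simplex chosen by exhaustive
grid search at step 0.05 (231 candidates) maximizing the validation metric;
the lexicographically first candidate wins ties, making the search
deterministic and order-independent.  Since the vertices are in the grid,
the combined validation score is never below the best single model.  The
weight on the ORIG-only model is the key introspection statistic: mass
there means the learned `<cls>` representation is being ignored.

## Evaluation

Split scenarios: `random` folds interactions; `unseen_odorant` /
`unseen_receptor` fold entities, with all of an entity's interactions in
the same test fold and an entity-respecting validation carve-out
(default 15% of the training portion).  Disjointness, coverage and entity
exclusion are property-tested over 100 random configurations.

Classification metrics use threshold 0.5 for precision/recall/F/MCC; MCC
returns 0 when any denominator factor is 0; AUROC and average precision come
from scikit-learn (rank statistic with tie averaging; step-interpolated PR
summation) and are cross-checked against independent formulations in the
tests; single-class truth vectors flag AUROC/AveP as missing rather than
propagate NaN.  Fold metrics are computed per fold and then averaged.

Model comparison over per-fold scores: paired t; one-way ANOVA with
Bonferroni-corrected Tukey post-hocs; or a Friedman test with
Benjamini–Hochberg correction over pairwise Wilcoxon signed-rank post-hocs.
Degenerate cases (identical scores, constant differences) are flagged
instead of returning unstable p-values.

## Synthetic data

Molecules come from a fixed template grammar (linear alkanes, alcohols,
aldehydes, methyl ketones, esters, ethers, amines, nitriles, and mono- and
para-disubstituted benzenes; 139 distinct SMILES), receptors are uniform
random 20-letter sequences.  Panels are full factorial; responses are
`u' M v` (bilinear; M rank-3 by default, emulating low-dimensional receptor
tuning) or `a·u + b·v` (linear in the concatenation, exactly fittable by the
MP model) on standardized count/k-mer features, rescaled so the noiseless
signal has unit variance, plus Gaussian noise of chosen SD.  Sparse screens
subsample the pair grid at a given density and threshold the planted score
at the empirical quantile hitting the target positive rate, with quality
tiers drawn from a supplied distribution — reproducing the class imbalance
that makes MCC and accuracy diverge.

What the generator does **not** emulate: real structure–activity
relationships, receptor sequence–function coupling, measurement artifacts,
or dataset-specific response distributions.  Passing tests establish that
the pipeline recovers signal it was designed to recover under controlled
conditions — correctness and calibration of the machinery, not predictive
validity on laboratory data.

## Problem sizes used in scripted runs

The acceptance script and heavy tests use a 50 × 40 panel (2,000 pairs,
noise SD 0.1) for transformer training, 40 × 15 panels for the ridge
recoveries, an 80 × 20 noiseless panel for the shape analysis, and 8–20
training epochs — sizes at which every qualitative recovery in this note is
comfortably reproducible on a single CPU.

## Known limitations

* No pre-trained encoder weights ship with the package; the HuggingFace-
  style attachment point is an interface, exercised only by the tiny
  built-in encoders.
* Stage-1 training is single-threaded, full-precision, and sized for
  desk-scale data; there is no distributed or mixed-precision path.
* The quality-tier → weight mapping is configuration, not a shipped
  reproduction of any published weighting scheme.
* Whether classification ensembles should combine probabilities or logits
  is a genuine convention choice; probabilities are used and documented.
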