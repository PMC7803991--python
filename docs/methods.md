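# Methods

`gcnqsar` implements a quantitative structure–activity (QSAR) regression
pipeline in which a graph convolutional network (GCN) predicts pIC50
directly from 2-D molecular structure, with database-style curation up
front and information-theoretic diversity diagnostics alongside. This note
documents the model, the procedures, the tunable parameters, the synthetic
benchmark, and the numerical and design choices a maintainer should know.

## Data model and curation

A raw activity table holds one assay measurement per row with the usual
activity-database columns (compound id, SMILES, `standard_type`,
`standard_value` in nM, units, relation, assay type, confidence score,
comment fields, duplicate flag, target id). Curation applies, in order:

1. **Row filters.** Keep rows with `standard_value > 0`, a pooled
   activity type in {IC50, EC50, Ki, Kd, Km}, confidence score ≥ 6 (the
   database's target-assignment confidence), binding assays
   (`assay_type = B`), values in nM, relation in {>, ≥, =, ≤, <},
   activity comment neither "Inconclusive" nor "Not determined",
   `potential_duplicates = 0`, and a validity comment other than
   "Potential author error". Each dropped row is charged to the first
   rule it fails, so the report's drop counts plus survivors plus
   standardization failures plus collapsed duplicates always equal the
   input row count — an exact bookkeeping invariant that is tested.
2. **Structure standardization.** The largest fragment by heavy-atom
   count (preferring carbon-containing fragments) is kept, simple
   protonated/deprotonated centres are neutralized with the standard
   SMARTS rule for non-zwitterionic ±1 atoms, and the RDKit canonical
   SMILES is emitted; strings over 1000 characters are rejected. The
   original workflow used a proprietary standardizer with a salt/solvent
   dictionary; this largest-organic-fragment + neutralization
   approximation is close but not dictionary-faithful, and tautomers are
   deliberately passed through unchanged. Failures are returned as
   values, never exceptions, so one bad row cannot abort a batch.
3. **p-activity transform.** pIC50 = 9 − log10(v/nM), i.e. −log10 of the
   molar value. (The worked anchor: 10 nM ↔ pIC50 = 8.)
4. **Deduplication.** One record per (canonical SMILES, target); the
   maximum (most active) pIC50 wins; ties keep the first occurrence in
   input order. Censored rows (relation > or <) are kept as-is and
   regressed as point values; the relation is stored for provenance only.

## Splitting

A seeded two-stage random split: 90% training-validation / 10% test, then
88.8% / 11.2% within the pool, giving ≈ 80:10:10 overall. Subset sizes
round half-away-from-zero, test count first. The input is order-normalized
(sorted by compound and target) before the seeded permutation, so the
split is a pure function of the record set, the seed and the fractions.
Random splitting only — the pipeline measures the consequence of random
splitting through the KLD diagnostic rather than enforcing
scaffold-disjoint splits.

## Featurization

Each heavy atom becomes a 75-bit binary vector: element one-hot over a
fixed 44-symbol list ending in "Unknown" (44), heavy-atom degree 0–10
(11), implicit valence 0–6 (7), formal-charge presence bit (1), radical
presence bit (1), hybridization one-hot {SP, SP2, SP3, SP3D, SP3D2} (5),
aromaticity flag (1), and total hydrogens 0–4 (5). Out-of-range
categories clamp to the last slot of their block (rare hybridizations map
to the SP3 slot), so every one-hot block carries exactly one set bit —
the layout stays strictly binary because charge and radical counts are
collapsed to presence bits. Hydrogens are implicit; bonds define an
undirected neighbour list. This is the de-facto standard graph-convolution
featurization; the exact feature table of the original workflow was not
recoverable, so this layout is an assumption matched to the documented
content and dimension.

## Network

For atom state h_v (initially the 75-bit vector):

* **Graph convolution**: h'_v = ReLU(BatchNorm(W_self·h_v +
  Σ_{u∈N(v)} W_nbr·h_u + b)). One shared W_nbr serves all neighbour
  degrees (the reference implementation family uses degree-specific
  weights; the shared form is simpler and is validated behaviourally on
  synthetic recovery, not weight-for-weight).
* **Graph pooling**: elementwise max over the closed neighbourhood
  {v} ∪ N(v). Conv + pool repeat L times, L ∈ {1, 2, 3, 4}.
* **Dense**: a linear layer applied atomwise.
* **Graph gathering**: the per-atom dense outputs are summed per molecule
  and passed through tanh — the molecule's "neural fingerprint".
* **Output**: a single linear neuron.

Training minimizes mean-squared error with Adam (β₁ = 0.9, β₂ = 0.999).
MSE is a choice: the original description says only that the loss was
minimized, and squared error is the standard choice for pIC50 regression.
Batch norm sits before the ReLU (placement was unspecified; pre-activation
is the common convention) with batch statistics during training and
running statistics (momentum 0.9, ε = 1e-5) at inference. Dropout, when
enabled, acts on each conv layer's post-ReLU output and on the atomwise
dense output, inverted-scaled at train time.

Two training regimes exist because the epoch count plays two roles:

* **Fixed-epoch** (hyperparameter search): the epoch count is itself a
  searched hyperparameter, so a trial trains exactly that many epochs and
  is scored on the validation set at the end.
* **Epoch-block** (final models): train in blocks of 100 epochs; stop
  when the running minimum validation MAE fails to strictly decrease
  during a block; no cap on total epochs. After stopping, the weights
  from the epoch with the maximum validation 2R2_MAE become the final
  model (ties go to the earliest epoch). Only the best-scoring snapshot
  and the current weights are retained in memory, since only the argmax
  is ever used.

## Metrics and model selection

MAE, RMSE and R² = 1 − RSS/TSS are the base metrics (MAE ≤ RMSE ≤
√n·MAE always; fuzz-tested). The selection score is

    2R2_MAE = (R² − MAE) + R²

— among settings with similar MAE it prefers the better R²; both terms
are on comparable scales because MAE sits in roughly [0, 1] for pIC50
models of this kind.

Hyperparameters are searched per depth tier — one conv layer, two, and a
grouped three-to-four tier (the layer count within the grouped tier is one
more categorical dimension). Each tier runs `n_repeats` independent
repeats; each repeat runs `n_iter` trials of Bayesian optimization
minimizing validation MAE, and the trial with the maximum 2R2_MAE becomes
that repeat's candidate. The optimizer is a Gaussian process with a
Matérn ν = 5/2 kernel and expected improvement, maximized over a random
candidate pool (built on scikit-learn's GP regressor); a uniform random
backend is available as a fallback and correctness never depends on the
backend, only efficiency. Sizes and learning rate are sampled
log-uniformly, dropout/epoch/batch uniformly.

Search ranges:

| hyperparameter | default | small datasets | desk scale |
|---|---|---|---|
| conv layer size | 32–2048 | 16–512 | 16–128 |
| dense layer size | 16–2048 | 16–512 | 16–128 |
| conv layers | 1, 2, 3–4 | same | same |
| learning rate | 1e-4–2e-3 | same | same |
| dropout | 0–0.5 | same | same |
| epochs (search) | 20–200 | same | 20–60 |
| batch size | 10–100 | same | same |

The desk-scale column is this package's own addition: the synthetic
benchmark datasets (~1000 compounds, planted additive signal) are well
inside the capacity of narrow networks, and the CPU-only NumPy backend
makes the wide ranges needlessly expensive there. The full-scale regime
of the original protocol is `n_iter=100`, `n_repeats=4`, all three tiers,
default ranges; the pipeline default is `n_iter=10`, `n_repeats=2`, tiers
{1, 2}, desk ranges.

Retention rules after the search: tier-1 candidates are always retained,
but if every tier-1 repeat has R² < 0.45 the tier is flagged for an
extended re-search (budget configurable; the full-scale protocol uses
1000 iterations, the pipeline default reuses `n_iter`). The re-search
augments the candidate pool rather than replacing it — both sets of
repeats are honest draws from the same search distribution, so discarding
the originals would only lose information. Tier-2 candidates need
R² ≥ 0.40; candidates of the 3–4 tier must beat every shallower retained
candidate's R².

Retained candidates are retrained from scratch with a fixed seed under
the epoch-block rule; this retraining doubles as the reproducibility
check: a model whose retraining validation R² falls more than `delta`
below its search-time R² is excluded as non-reproducing. `delta`
defaults to 0.15 — chosen to separate a genuine collapse (e.g. 0.53 →
0.16) from benign seed-to-seed fluctuation; "a reasonable range" was
never quantified in the original description, so the rule is an explicit,
configurable stand-in. If the filter would exclude every candidate, the
pipeline keeps the single best-retraining model with a warning, since an
ensemble needs at least one member.

The ensemble prediction is the unweighted mean of member predictions. Two
exact consequences are asserted in tests: ensemble MAE ≤ mean member MAE
(triangle inequality per sample) and ensemble MSE ≤ mean member MSE
(variance decomposition of mean ensembles).

## Scaffold diversity

The carbon skeleton of a compound is its Murcko framework — ring systems
plus connecting linkers, side chains removed — with every heavy atom
replaced by carbon and every bond by a single bond (bond orders were
unspecified in the source description; all-single is this package's
interpretation, and it makes skeletons fixed points of the operation).
Acyclic molecules map to a designated empty skeleton of size 0 that sorts
first — every compound must land in a bin for the histogram to normalize.

A reference skeleton list is sorted ascending by size with a
canonical-SMILES tiebreak (the tie order was unspecified; the tiebreak
only moves bin boundaries between equal-size scaffolds) and chunked into
bins of fixed capacity — 10,000 per bin at database scale, where 145,515
scaffolds give 15 bins with 5,515 in the last; the desk-scale default
derives the capacity so that ~15 bins result. A dataset's histogram
counts compounds (not scaffolds) per bin, p_i = c_i/c. Skeletons absent
from the reference map to the bin their (size, SMILES) sort position
brackets, so new datasets are scorable against a fixed reference.

Diversity is Shannon entropy H = −Σ p_i log2 p_i (max log2 15 = 3.91
bits for 15 bins); split-induced distribution shift is the
Kullback–Leibler divergence KLD(p‖q) = Σ p_i log2(p_i/q_i) of a subset p
against the unsplit dataset q. KLD is non-negative and zero iff p = q.
Because random splits of small datasets routinely empty some bins, q
receives additive smoothing ε = 1/(10·c) by default (c = q's compound
count); with smoothing off, unsupported mass yields an infinite
divergence, reported as such.

## Virtual screening

Candidates are filtered by Crippen atomic-contribution logP >
`logp_min` (default 2.0), predicted target pIC50 ≥ 7.5, predicted
anti-target pIC50 ≤ 6.0, and absence from a user-supplied
excluded-compounds set (prior assay reports against related targets);
hits are ranked by descending target prediction, stable on ties, each
carrying its per-criterion values for audit. The original workflow's logP
came from a proprietary calculator, so checks against its reported values
use a ±0.5 method-mismatch tolerance. Screening stops at the ranked audit
table — visual inspection and purchasability are outside the computable
contract. Infinite thresholds disable the corresponding filter and skip
the potency>anti-target window sanity check.

## Synthetic benchmark

The generator assembles molecules from 13 ring scaffolds (skeleton sizes
5–17, uniform sampling weights) by attaching 0–3 substituents from a
20-fragment library at random scaffold carbons with a free valence; every
generated SMILES is chemically valid by construction. The planted SAR is
additive: true pIC50 = baseline (6.0) + Σ w_f per attached fragment, with
w_f spanning [−1.5, +1.5]. Measurements add Gaussian noise (default sd
0.3, a plausible inter-laboratory reproducibility scale for heterogeneous
IC50 data) and are emitted as nM values. Corruption knobs, all exact
quotas and all driven by one seed: `junk_fraction` rows each violate
exactly one curation filter (cycling through low confidence, wrong units,
banned comment, duplicate flag, bad validity comment, wrong assay type,
corrupted SMILES); `duplicate_fraction` rows re-emit an existing compound
with fresh noise; `censor_fraction` rows are clamped to assay limits
(v ∈ [0.1, 1e6] nM ↔ pIC50 ∈ [3, 10]) with relation < or >; every sixth
clean row is written as an HCl salt adduct to exercise salt stripping.
Base compounds are unique by canonical SMILES, so survivor counts are
exactly predictable: n − junk − duplicates.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, activity cliffs, correlated assay noise,
scaffold-hopping structure, or any resemblance to a real database's
scaffold histogram. Passing the end-to-end test therefore shows that the
pipeline's machinery — curation, search, block-rule training, selection,
ensembling — correctly recovers a learnable signal at realistic noise; it
does not certify predictive performance on real pharmacological data.

A second harness, the scaffold-profile generator, draws compounds whose
skeletons fall in prescribed bins of a binning scheme (multinomial over
bin probabilities), using an enumerated library of carbon skeletons
(single rings and linker-joined ring pairs); it exists to test H and KLD
behaviour with known ground truth.

## Numerical implementation

No neural-network backend is assumed: the network, batch-norm, dropout,
Adam and backpropagation are implemented on NumPy/scipy.sparse in
float32, with numba kernels for the segment operations (closed-
neighbourhood max-pool with explicit argmax for the backward pass,
per-molecule segment sums, fused batch-norm statistics and
BN→ReLU transforms, Adam updates). Mini-batches are formed once from a
seeded shuffle and their order is reshuffled each epoch, so per-batch
graph structures (sparse adjacency, pooling and gathering indices) are
built exactly once. Batch-norm variance uses the two-pass form — the
single-pass E[z²]−E[z]² form cancels catastrophically in float32.
The max-pool subgradient routes to the first argmax.
Training is bitwise-reproducible for a fixed seed on a given platform;
correctness of the backward pass is pinned by an independent dense
float64 reference implementation and by finite differences along the
smooth output path (the conv bias has a true gradient of ~0 under batch
norm and is excluded from comparisons).

Desk-scale problem sizes used by the test suite: the end-to-end benchmark
runs n = 1000 compounds, noise sd 0.3, 10 search iterations × 2 repeats ×
tiers {1, 2} on the desk ranges, block-rule retraining without an epoch
cap, over 5 generator seeds; unit tests use 120–400 compounds.

## Known limitations

* The structure standardizer approximates, not replicates, the
  proprietary tool used for the original extract; neutralization covers
  simple acids/bases only.
* The 75-bit feature layout is the standard one, asserted by content and
  dimension, not by the original feature table.
* Degree-specific convolution weights are not implemented (shared
  W_nbr).
* GPU execution, multi-task heads and uncertainty estimates are out of
  scope; the NumPy backend is single-process and CPU-bound, practical to
  a few thousand compounds and hidden sizes of a few hundred.
* The reproducibility `delta` and the desk-scale search ranges are this
  package's choices, documented above, not published values.
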