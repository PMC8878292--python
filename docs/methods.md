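# Methods

## Scope and model

`pnaqsar` implements a multitask regression model for ligand potency
(pIC50, the negative decadic logarithm of IC50 in molar units) against
seven receptor tyrosine kinases (ALK, EGFR, ERBB2, ERBB4, MET, RET, ROS1),
plus the data pipeline around it. The model assumes that the seven tasks
share transferable structure–activity signal — reasonable for one protein
family with overlapping chemical space — and exploits it through hard
parameter sharing: every layer is shared except one final linear head per
task. Compounds may carry labels for any subset of tasks; missing labels
are masked out of the loss, never imputed.

### Graph branch

A molecule is a directed graph over heavy atoms; every bond contributes
both directed edges. Atom rows are 30-dimensional (element one-hot over
C/N/O/S/F/Cl/Br/I/P/other, degree one-hot 0–5, formal-charge sign,
hybridization one-hot sp/sp2/sp3/other, aromaticity, ring membership,
total-H count one-hot 0–4); bond rows are 75-dimensional (bond-type
one-hot, conjugation, ring membership, stereo one-hot, ring-size flags
3–8, zero-padded to the fixed width). The message for edge (j→i) is an MLP
of [x_i, E_{j→i}, x_j]. Messages into a node are reduced by four
aggregators — mean, population standard deviation, maximum, minimum — each
scaled by three degree scalers

    S(d, α) = (ln(d+1)/δ)^α,  α ∈ {0, +1, −1},
    δ = mean of ln(d_i + 1) over all atoms of all training graphs,

and the 12 blocks are concatenated before the node-update MLP
(update = MLP([x_i, aggregation])). Natural logarithms are used
throughout. Two conventions deserve note:

* δ averages over *atoms pooled across training graphs*, not per-graph
  means; this makes δ independent of how molecules are batched.
* Isolated atoms (d = 0, e.g. methane's carbon) receive S = 1 for every α,
  extending the d > 0 definition continuously instead of dividing by
  log(1) = 0.

Node embeddings are sum-pooled into the molecule embedding (mean pooling
is selectable via `pooling="mean"`; sum performed better in our synthetic
calibration runs and is the default).

### Descriptor branch

Sixteen boolean fingerprint families are concatenated into one block:
MACCS (167), E-state (79), Avalon (512), ECFP2/4/6 and FCFP2/4/6 (1024
each), RDKit path fingerprints with maximum path 5/6/7 (1024 each),
atom-pair, topological-torsion, layered and pattern fingerprints (1024
each) — 14 070 bits total, all computed with RDKit. The roster is a
configurable registry, and the active roster is stored in every checkpoint
so a model cannot silently be applied with mismatched features. The block
is reduced by PCA fitted on the training split only, keeping the smallest
number of components whose cumulative explained variance reaches 95%
(`variance_target`). Components are then standardized to zero mean and
unit variance (training statistics); this materially improved optimization
of the dense branch. We concatenate all families before a single PCA
rather than reducing per family; the alternative is a one-line change in
`FeatureReducer` usage but is not exposed.

### Fusion, loss, training

The pooled graph embedding and the dense-branch output are concatenated
and passed through fully connected layers into T linear heads. The loss is

    L = Σ_t (1/n_t) Σ_{i: labeled for t} (ŷ_it − y_it)²

with n_t the number of labeled examples for task t *within the batch*;
tasks absent from a batch contribute zero. Optimization is Adam with L2
regularization (weight decay added to the gradient), mixed mini-batches
drawn in seeded random order each epoch. Early stopping: training halts
after `patience` (default 10) consecutive epochs in which neither the
validation loss nor its `window`-epoch (default 10) moving average
improves on its best value; the weights of the best-validation epoch are
restored. The stopping rule is factored into `EarlyStopping` /
`early_stop_epoch` so it can be traced on scripted loss sequences.

Default architecture and schedule (`PNAMultitaskRegressor`): one PNA layer,
message MLP width 16, node embedding 48, dense branch 96, fusion layer 64,
learning rate 5e-3, weight decay 1e-5, batch size 32, at most 100 epochs,
dropout 0. These were chosen once on synthetic calibration runs at the
problem sizes below and are all exposed as estimator parameters and YAML
config keys; no automated hyperparameter search is shipped.

The network and its reverse-mode autodiff tape (`pnaqsar._autograd`) are
pure NumPy. The tape implements exactly the operations the architecture
needs (dense algebra, gather, segment sum/mean/max/min/std); gradients of
the extremum aggregators use the tie-sharing subgradient, and the
population-std aggregator adds an epsilon (`std_eps`, default 1e-8) under
the square root only where the variance is strictly positive, so
single-message segments have exactly zero std and no gradient blow-up.

## Curation

Raw records (SMILES, target, IC50 or pIC50, source, assay text, optional
ChEMBL-style properties) pass through:

1. unit conversion to pIC50; non-positive IC50 rejected with a reason code;
2. desalting (largest fragment by heavy-atom count, ties by molecular
   weight then lexicographic SMILES) and canonicalization; unparsable
   SMILES are counted and rejected, never raised mid-pipeline;
3. optional assay-text regex filter (config), since source schemas differ;
4. within-source deduplication: exact (assay, value) duplicates collapse;
   conflicting values keep the lowest IC50 (highest pIC50);
5. per-target IQR outlier filter on molecular weight, logP and rule-of-five
   violations: a record is removed iff any property falls outside
   [Q1 − 3·IQR, Q3 + 3·IQR]. Quartiles use linear interpolation between
   order statistics; missing properties pass with a logged warning;
6. cross-source merge keyed by canonical SMILES, keeping the higher pIC50
   per compound–target;
7. task labels: a multitarget compound is labeled with its rarest target
   (global counts; ties broken by the fixed target order);
8. stratified split per task label: 10% external test first, then 10% of
   the remainder to validation; labels with fewer than 3 compounds go
   entirely to train with a warning;
9. activity-cliff generator removal, strictly on the train–validation pool.

An activity-cliff pair is two same-target compounds with ECFP4 (radius 2,
2048 bits) Tanimoto ≥ 0.9 and |ΔpIC50| ≥ 1.0. A generator is a compound in
at least one pair whose mean activity–similarity difference — mean over its
pairs of |ΔpIC50| − (1 − T) — exceeds zero. Generators lose that target's
label; the procedure iterates until no pair remains. All three thresholds
are config keys and every removal is logged, so alternative cliff
definitions can be audited or swapped in. The external test set never
participates in cliff removal, PCA fitting, δ estimation or AD calibration
(asserted by integration tests).

## Validation

RMSE and R² follow the standard definitions (R² against the observed mean).
Internal validation is label-stratified k-fold (k = 10 by default,
implemented as per-label seeded round-robin so rare labels degrade
gracefully); RMSECV and Q² are computed on the pooled out-of-fold
predictions rather than averaged per fold. The external-test
Golbraikh–Tropsha gate requires all of

    Q² > 0.5,  R² > 0.6,  (R² − R0²)/R² < 0.1,
    0.9 ≤ k ≤ 1.1,  |R0² − R0′²| < 0.3,

where R0² (R0′²) is the coefficient of determination of the through-origin
trendline with predictions (observations) on the X-axis and k the
through-origin slope of observed on predicted. The relative-R0 condition
uses the predicted-on-X orientation; both orientations are reported.

## Applicability domain

Stage 1 (global structural overlap): the query's maximum ECFP4 Tanimoto
similarity to all training compounds must reach a calibrated threshold.
Calibration per CV fold: keep holdout compounds whose squared error is
within the third quartile of the fold's squared-error distribution (read
as "the best-predicted 75%"; the strict Q2–Q3 band is available via
`q3_band=True`), z-score their nearest-neighbor similarities, take the
minimum similarity among compounds with |z| ≤ 1.96 (two-sided 95%;
one-sided is a flag), and average the per-fold minima.

Stage 2 (neighborhood reliability): training compounds labeled for the
target with Tanimoto ≥ 0.35 to the query are its target neighbors; the
mean of their CV squared residuals must fall below a per-target cutoff of
10% of the target's training pIC50 range. Because a mean *squared*
residual and a pIC50 range are dimensionally incommensurate, the default
comparison is on the root scale (√msr < 0.10 × range); the literal
squared-scale comparison is available via `squared_scale=True`. A query
with zero neighbors fails stage 2 — no evidence of reliability is treated
as unreliable. "Inside" requires both stages; raising the global threshold
can only shrink the inside set (tested property).

## Synthetic data

The generator (`pnaqsar.synthetic`) assembles molecules from a fixed
grammar: 18 kinase-inhibitor-like heteroaromatic cores × 15 small
substituents × 12 larger arms, attached at the first and last aromatic CH
carbons. True activity is additive in the parts (or, optionally, linear in
six standardized physchem descriptors), with per-part coefficients mixed
from a shared and a target-specific component so the cross-target truth
correlation is tunable (`design_correlation`, default 0.8, verified to
±0.1 at n = 500). Observed labels add Gaussian noise (default 0.3 pIC50
units — a typical inter-assay reproducibility figure); truths are clipped
to the 4–10 pIC50 range seen in public kinase data. Requested fractions of
salts, exact duplicates, conflicting duplicates and engineered activity
cliffs are injected on top; cliff pairs use a symmetric triaryl-benzene
template in which swapping one arm leaves the circular-fingerprint bit set
essentially unchanged (pair Tanimoto verified ≥ 0.9 at generation time)
while the truth differs by ≥ 2 pIC50 units, so the cliff detector provably
can find them. An "alien" grammar variant (different cores and aliphatic
arms) supports applicability-domain studies.

What the generator does *not* emulate: realistic medicinal-chemistry
plausibility, assay-specific noise structure, target-dependent chemotype
bias, or the long-tailed label imbalance of public databases (coverage is
Bernoulli per target). Passing tests therefore demonstrate the machinery
is correct and the method behaves as designed under controlled conditions,
not that the quantitative performance transfers to real ChEMBL/BindingDB
corpora.

## Benchmark study designs (scripts/acceptance.py, tests/test_acceptance.py)

Sizes were fixed once so a full run stays in the minutes range on one CPU:

* **Learning sanity** — 20 seeds; per seed a 500-compound 2-task library
  (noise 0.3), curated and split 10% external; the multitask model's
  pooled external RMSE is compared with the per-target training-mean
  baseline, and the mean per-target external R² is recorded for the first
  10 seeds.
* **Multitask transfer** — 10 seeds; 470 compounds with task coverage 0.9
  vs ~0.085 (≈40 labels) and truth correlation 0.9. A quarter of the
  small task's compounds are held out entirely; multitask (both tasks) and
  single-task (small task only) models are scored on them; medians over
  seeds are compared.
* **AD behavior** — 10 seeds; 320-compound training pool from 14 cores,
  60 alien compounds from the held-back cores and alien arms. Threshold
  calibration uses k = 3 folds (a size/time compromise; the calibration
  procedure itself is fold-count-agnostic). External RMSE is pooled by
  verdict over the in-domain external split plus the alien set.
* **Cross-validation reference** — one 300-compound library, k = 10,
  pooled RMSECV and per-task Q².

## Numerical choices and degenerate inputs

* Tanimoto of two all-zero keys is defined as 0 with a warning.
* PCA with `variance_target=1.0` keeps exactly the numerical rank.
* Zero-variance observations make R² undefined; the functions raise rather
  than return a sentinel.
* A fold with fewer than 4 compounds is skipped in threshold calibration;
  if all folds are skipped, calibration fails loudly.
* Training aborts with a diagnostic on non-finite loss.
* Checkpoints store weights, δ, the PCA reducer, feature standardization,
  fingerprint roster, target order, config and training log; loading
  verifies roster and target order and refuses on mismatch.

## Known limitations

* The NumPy network is CPU-bound and sized for datasets of 10²–10⁴
  compounds; it makes no attempt at GPU-scale throughput.
* Node/bond featurization is fixed-width (30/75) by contract; exotic
  elements map to "other".
* Single-task baselines (RF/GBRT/GCN/GAT) are out of scope; the estimator
  API is sklearn-compatible precisely so such comparisons are easy to run
  externally.
* The applicability domain is similarity-based only; leverage or
  density-based variants are not provided.
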