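# pnaqsar

Multitask QSAR for receptor tyrosine kinase inhibitors: a principal
neighborhood aggregation (PNA) graph network fused with a fingerprint-based
deep network predicts pIC50 against seven kinase targets — ALK, EGFR, ERBB2,
ERBB4, MET, RET, ROS1 — simultaneously, together with the surrounding
pipeline a practicing QSAR modeler needs: activity-record curation,
activity-cliff removal, stratified validation with the Golbraikh–Tropsha
acceptability criteria, and a two-stage Tanimoto applicability domain for
screening.

It is written for computational chemists screening multitargeted candidates
(e.g. for nonsmall cell lung cancer programs, where approved drugs such as
crizotinib inhibit several of these kinases at once) and for method
developers who want a compact, dependency-light reference implementation of
the PNA + descriptor fusion architecture.

## The model

Molecules enter through two branches.

**Graph branch (PNA).** Each molecule is a directed graph with 30-dim atom
features and 75-dim bond features. A message from neighbor *j* to atom *i*
is MLP([x_i, E_{j→i}, x_j]); incoming messages are combined by four
aggregators (mean, population std, max, min), each modulated by three degree
scalers

    S(d, α) = (ln(d+1) / δ)^α ,   δ = mean over training atoms of ln(d+1),

with α ∈ {0, +1, −1} (identity, amplification, attenuation), giving 12
concatenated blocks that feed the node-update MLP; summed node embeddings
give the molecule embedding.

**Descriptor branch.** Sixteen boolean fingerprint families (MACCS, E-state,
Avalon, ECFP/FCFP at three radii, path-based, atom-pair, torsion, layered,
pattern) are concatenated and PCA-reduced to retain 95% of training-set
variance, then passed through a dense network.

The branches are fused through fully connected layers into one linear head
per target (hard parameter sharing). Training minimizes the masked
multitask loss

    L = Σ_t (1/n_t) Σ_{i: labeled} (ŷ_it − y_it)² ,

with Adam + L2, stopping early when neither the validation loss nor its
10-epoch moving average has improved for 10 epochs.

A prediction is flagged "inside" the applicability domain for a target iff
(1) the query's nearest-neighbor ECFP4 Tanimoto similarity to the training
set reaches a threshold calibrated from cross-validation residuals, and
(2) the mean squared CV residual of its target-labeled neighbors
(Tanimoto ≥ 0.35) stays below 10% of the target's training pIC50 range.

## Worked example

```python
import numpy as np
from pnaqsar.synthetic import SyntheticSpec, generate_library
from pnaqsar.model import PNAMultitaskRegressor
from pnaqsar.validation import rmse, r_squared

spec = SyntheticSpec(n_compounds=500, targets=("T1", "T2"), noise_sd=0.3, seed=0)
_, truth = generate_library(spec)
smiles = truth.table["smiles"].tolist()
Y = truth.table[["true_T1", "true_T2"]].to_numpy() \
    + np.random.default_rng(0).normal(0, 0.3, (len(smiles), 2))

est = PNAMultitaskRegressor(targets=("T1", "T2"), seed=0)
est.fit(smiles[:450], Y[:450])
pred = est.predict(smiles[450:])
for t in range(2):
    print(f"T{t+1}: RMSE {rmse(pred[:, t], Y[450:, t]):.3f}  "
          f"R2 {r_squared(pred[:, t], Y[450:, t]):.3f}")
```

prints:

```
T1: RMSE 0.547  R2 0.746
T2: RMSE 0.476  R2 0.714
```

i.e. on a 500-compound synthetic two-task library with 0.3 pIC50 units of
observation noise, the fused model explains ~75% of held-out activity
variance — comfortably above the R² > 0.6 bar that the Golbraikh–Tropsha
criteria set for an acceptable QSAR model.

The shell workflow mirrors the library:

```bash
qsar curate --in raw.csv --out curated/ --config cfg.yaml
qsar train  --data curated/ --out model.ckpt --config cfg.yaml
qsar cv     --data curated/ --folds 10 --out report.json
qsar screen --model model.ckpt --in library.csv --out predictions.csv
```

`predictions.csv` carries one row per input SMILES: seven `pIC50_<target>`
columns, seven `AD_<target>` columns with the literal values
`inside`/`outside`, and a parse status.

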