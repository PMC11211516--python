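# combosyn

Prediction of drug-combination synergy in cancer cell lines from gene
expression and molecular structure.

Anticancer drug pairs are screened against cell-line panels, and each
(drug A, drug B, cell line) triple is scored against four reference null
models — Loewe additivity, Bliss independence, HSA and ZIP. A pair is
*synergistic* when its combined effect exceeds the null expectation and
*antagonistic* when it falls short. `combosyn` trains a classifier that
predicts this outcome from two inputs: the cell line's landmark-gene
expression profile and the two drugs' SMILES structures.

## Model

**Cell branch — kernel-density image of the expression vector.** A cell
line's 496-gene expression vector is split evenly into halves *x* and *y*;
the 248 paired values are treated as a 2-D point cloud and smoothed with a
bivariate Gaussian KDE on a G×G equidistant grid,

```
f(X_p, Y_q) = 1/(n h²) · Σ_m K((X_p − x_m)/h, (Y_q − y_m)/h),
K(u, v)     = (1/2π) · exp(−(u² + v²)/2),
```

with bandwidth *h* from Scott's rule by default. The grid's min–max
normalized coordinates are attached as two positional-encoding channels,
and the 3×G×G stack is encoded to `z_e` by a residual CNN (bottleneck
units, PReLU activations; the full preset stacks 3/4/6/3/3 units over five
downsampling stages).

**Drug branch — graph attention over the molecule.** Each drug is an R×9
atom-feature matrix (atomic number, chirality, degree, formal charge, H
count, radical electrons, hybridization, aromaticity, ring flag) plus a
binary adjacency matrix. Stacked GATv2 layers update the atom states with
dynamic attention

```
α_ij = softmax_{j ∈ N_i ∪ {i}} ( aᵀ LeakyReLU(Θh_i + Θh_j) ),
h_i' = ELU( Σ_j α_ij Θ h_j ),
```

each layer's states are global-average-pooled into `g^l`, and a learned
context vector attends over the layers: `ψ = softmax(c·g^l / √d′)`,
`z = Σ_l ψ_l g^l`. GAT and GCN variants are available for comparison.

**Fusion.** `[z_e ∥ z_a ∥ z_b]` feeds a two-hidden-layer feedforward
classifier (ReLU, dropout, 2-way log-softmax), trained by negative
log-likelihood with Adam under stratified 5-fold cross-validation,
reporting AUC, AUPR, ACC (and PCC/RMSE from an optional regression head).

**Labels.** A combination is admitted only when all four synergy scores
agree in sign against their thresholds (default 0): unanimously above →
positive, unanimously below → negative, anything else excluded.

Because the public synergy databases (GDSC, DrugComb, NCI ALMANAC) are not
bundled, the package ships a synthetic-data generator that emulates all
three input tables with a planted, documented synergy signal — see
`docs/methods.md` — so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from combosyn import (SimConfig, simulate_tables, assemble_dataset,
                      DatasetConfig, SynergyModel, TrainConfig)

cfg = SimConfig(n_cells=10, n_drugs=16, n_triples=200, seed=7).easy()
expression, drugs, combinations = simulate_tables(cfg)
dataset = assemble_dataset(expression, drugs, combinations,
                           DatasetConfig(grid_size=32))
print(f"{len(dataset)} labeled combinations "
      f"({dataset.provenance['n_excluded']} excluded by the consensus rule)")

model = SynergyModel(dataset, TrainConfig.tiny(num_epochs=40))
idx = np.random.default_rng(0).permutation(len(dataset))
results = model.fit(seed=0, train_idx=idx[:160], val_idx=idx[160:])
print(results.summary())
```

prints

```
192 labeled combinations (8 excluded by the consensus rule)
Synergy classifier fit
==============================================
samples: 192   epochs: 40   batch: 600
branches: dkpe=True gnn=True (gatv2, L=3, d=32)
loss: 0.6956 → 0.2749
----------------------------------------------
metric        mean        sd
auc         0.9069    0.0000
aupr        0.9375    0.0000
acc         0.7812    0.0000
```

200 simulated triples yield 192 usable samples after the four-score
consensus filter drops 8 sign-discordant records. Forty epochs of the
desk-scale preset reduce the training loss from chance level (log 2 ≈
0.693) to 0.27, and the 32 held-out combinations are ranked with AUC 0.91:
the model has recovered the generator's planted drug–drug × cell-line
synergy structure from the density images and molecular graphs alone.

The same pipeline is scriptable from the shell:

```
combosyn simulate --n-cells 20 --n-drugs 30 --n-triples 600 --seed 0 --out sim/
combosyn train --expression sim/expression.tsv --smiles sim/drugs.tsv \
               --combinations sim/combinations.csv --checkpoint model.npz
combosyn predict --checkpoint model.npz --expression sim/expression.tsv \
                 --smiles sim/drugs.tsv --pairs pairs.csv --out preds.csv
```

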