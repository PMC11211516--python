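# Methods

## The prediction task

Given a cell line's normalized landmark-gene expression vector (496 genes
by default) and two drugs' SMILES structures, predict whether the
combination is synergistic or antagonistic. Ground-truth class labels come
from four synergy scores per combination (Loewe, Bliss, HSA, ZIP); a
sample is used only when all four agree (unanimously above their
thresholds → positive, unanimously below → negative, otherwise excluded).
Thresholds default to 0 — the natural sign convention of synergy scores —
and are independently configurable, since other studies draw the line
elsewhere. The package consumes scores as given; it does not compute them
from dose–response surfaces.

## Cell-line featurization: density map + positional encoding

The expression vector is split evenly into two halves; the i-th entry of
each half forms a point (x_i, y_i). The bivariate Gaussian KDE of these
pairs is evaluated on a G×G equidistant grid:

    f(X_p, Y_q) = 1/(n h²) Σ_m K((X_p−x_m)/h, (Y_q−y_m)/h),
    K(u,v) = (1/2π) exp(−(u²+v²)/2).

This map is asymmetric in the two halves — swapping them transposes it
(f_xy(p,q) = f_yx(q,p)) — which the tests use as the checkable form of the
map's directionality.

Choices that the definition leaves open, and what this package does:

- **Bandwidth** `h`: Scott's rule for bivariate data, h = n^(−1/6)·σ,
  with σ the mean of the two per-axis standard deviations, floored at
  1e−6·(data range + ε) so constant vectors remain well-defined. An
  explicit override is accepted everywhere a bandwidth is.
- **Grid**: G = 64 by default (32 in the desk-scale training runs); axes
  span [min − 3h, max + 3h] per half, which keeps ≥ 99.7 % of every
  kernel's mass on the grid. A ±4h grid integrates to 1 within 0.02,
  which is the tested normalization tolerance.
- **Orientation**: `density[p, q]` is the value at `(x_coords[p],
  y_coords[q])` — the row index runs along the x (first-half) axis. Stated
  here to prevent silent transposes.
- **Positional encoding**: each axis's coordinates are min–max normalized
  to [0, 1] and broadcast into two G×G planes (one per axis). A pair of
  coordinate channels, not one interleaved channel, so the encoder sees
  both axes directly.
- **Channel stack**: the model consumes the numeric 3×G×G tensor
  (density, optionally min–max rescaled to [0, 1] so the three channels
  share a range, plus the two PE planes). Rasterized PNG images are a
  visualization utility only — rendering through a colormap would
  discretize the density and bake in resolution and palette artifacts,
  while the numeric tensor carries the same information exactly.
- **Expression normalization**: per-gene z-score across cell lines at
  table load, configurable off.

## Cell encoder

A residual CNN over the 3-channel tensor: a 3×3 stride-1 stem (a strided
large-kernel stem would discard most of a small grid), then five stages of
bottleneck units (1×1 reduce → 3×3 → 1×1 expand, batch-norm after every
convolution, PReLU with per-channel slopes initialized at 0.25). The first
unit of each stage downsamples spatially by 2, so inputs need G ≥ 32. Two
presets:

| preset | units/stage | stage channels | use |
|---|---|---|---|
| `resnet54-paper` | 3,4,6,3,3 (19 units) | 64/128/256/512/512, expansion 4 | full-scale configuration |
| `tiny` | 1,1,1,1,1 | 16/32/32/64/64, expansion 2 | one-CPU training; used by tests |

Global average pooling and a linear head produce `z_e`. Batch-norm keeps
running statistics for evaluation mode and is toggleable; the optional
per-stage fully-connected (squeeze-excite-style) blocks are off by
default because their intended form is not recoverable from the
architecture's description.

## Drug featurization and graph encoder

Heavy atoms are nodes; hydrogens enter through the total-H-count column.
The nine atom features are atomic number, chirality code (0 none / 1 CW /
2 CCW / 3 other), heavy-neighbor degree, formal charge, total H count,
radical electrons, hybridization code (0 s … 5 sp³d², 6 other),
aromaticity and ring membership. Adjacency is binary regardless of bond
order. Integer codes are passed raw to a learned bias-free linear
projection (9 → emb_dim); the projection absorbs scale.

The default encoder stacks L = 3 GATv2 layers of width emb_dim (100 at
full scale, 32 in the desk-scale preset), single-head by default. The
attention logit applies one shared linear map Θ to both endpoints —
`aᵀ LeakyReLU(Θh_i + Θh_j)` with LeakyReLU slope 0.2 — which keeps Θ at
emb_dim × d and makes the update `h_i' = ELU(Σ_{j∈N_i∪{i}} α_ij Θ h_j)`
(ELU α = 1, applied after every layer including the last). The self-loop
lives in the softmax's index set, not in the adjacency matrix. Multi-head
attention averages head outputs so the width never changes.

Readout is hierarchical: per-layer global average pooling `g^l`
(l = 1..L; the raw projected input is excluded), scores
`c·g^l / √d′` with a learned context vector c, softmax weights ψ, and
`z = Σ ψ_l g^l`. The two drugs share one encoder (the natural reading of
a single drug-graph module), switchable to separate weights.

GAT (separate per-endpoint attention vectors; static attention) and GCN
(symmetric-normalized convolution) variants implement the same interface
and pass the same invariance tests.

## Fusion head and training

`[z_e ∥ z_a ∥ z_b]` → two hidden layers (defaults 1024/512 full-scale,
512/256 desk-scale) with ReLU and dropout (0.5 / 0.2) → 2 logits →
log-softmax; negative log-likelihood, Adam (lr 1e−3 full-scale, 3e−3
desk-scale), fixed epoch count, no early stopping. An optional scalar
regression head shares the trunk and adds a small MSE term (weight 0.01,
because raw synergy scores are O(10)) to supply PCC/RMSE; classification
remains the primary objective since the two framings (regress-then-
threshold vs. direct two-class softmax) coexist in the protocol and the
classification head is the one whose output feeds the decision.

A combination is an unordered pair, but concatenation is order-sensitive.
Training therefore presents every batch in both drug orders (entity
encodings are shared between the two passes), and prediction averages the
two orders' probabilities.

Cross-validation is stratified by label: shuffled per-class indices are
dealt round-robin with the rotation carried across classes, so overall
fold sizes are balanced to ±1 and each class to ±1 per fold, for any n
and k. Every sample validates exactly once.

Ablation switches replace a disabled branch with a minimal-information
stand-in: with the density branch off, the raw expression vector passes
through a two-layer perceptron; with the graph branch off, each drug is
its mean-pooled 9-feature atom matrix through a linear map. All four
variants run under identical fold partitions and seeds.

## The synthetic benchmark

The generator emits the three input tables with a known planted signal.

- **Expression**: each cell line owns three 2-D Gaussian-mixture centers
  drawn from U(−3, 3)²; every (first-half, second-half) gene pair samples
  its mean from one of them (component jitter sd 0.4), so each cell
  line's paired point cloud — and hence its density map — is a distinct
  blob pattern.
- **Drugs**: a seeded panel from a packaged library of 164 valid SMILES.
  A fixed share of the panel (⌊n/4⌋ families of three, 7 families for the
  default 30-drug panel) consists of *skeletal-isomer families*: same
  molecular formula and heavy-bond count, different branching or
  heteroatom placement. Members of one family have exactly equal
  column-mean atom features, so a mean-pooled composition summary cannot
  tell them apart, while their per-atom rows and graphs differ — part of
  the planted signal is therefore carried by structure that only a graph
  encoder can see. This mirrors real panels, which contain close
  analogues that composition summaries collapse.
- **Planted synergy**: each drug gets a unit-norm latent t_d by blending
  a fixed random projection of its 64-bin hashed substructure-count
  fingerprint (raw counts — smooth, size-dominated, readily learnable
  structure) with a 0.35-weighted projection of the panel-standardized,
  ±3-clipped bin z-scores (which resolve fine structure, including the
  isomer families). Each cell line gets a unit-norm latent u_c from a
  fixed projection of its expression row. The latent synergy is

      s_raw = t_A·t_B + u_c·(t_A + t_B),

  standardized over the generated triples (median-centered so classes
  balance near 50/50), scaled by `effect_size` and perturbed with
  N(0, noise_sd²). The fingerprint is hashed with CRC-32 (stable across
  runs) and is deliberately independent of the learned encoder, so the
  ground truth cannot leak the model's own representation.
- **Four scores**: the latent score × 10 (putting values in the usual
  ±tens range) under independent multiplicative log-normal jitter
  (sd 0.15), which preserves sign — so with `discordant_frac = 0` no
  record is excluded. A `discordant_frac` fraction of records has one
  randomly chosen score's sign flipped to exercise the consensus filter.

Defaults are the desk-scale study conditions: 20 cell lines, 30 drugs,
600 triples, 496 genes, effect 2.5, noise 0.5, discordant fraction 0.1.
`SimConfig.easy()` (effect 4.0, noise 0.25, discordant 0.05) is the
strong-signal setting used by the verification suite; under it the tiny
presets reach held-out AUC ≈ 0.90–0.92 and a label-permutation control
falls to chance.

**What passing these tests does and does not show.** The generator's
entities are few (tens), every entity is seen in training, and the signal
is a low-rank bilinear form — so recovery demonstrates that the pipeline
can extract cell identity from density images and drug structure from
graphs and combine them, not that it matches benchmark accuracy on real
screens. Real data add dose–response measurement noise, batch effects,
many more entities and cold-start generalization, none of which the
generator emulates. For the same reason the branch-ablation gaps are
small at this scale: with all entities observed, the minimal stand-in
featurizers recover most entity identity, and the expected ordering
(complete ≥ single-branch ≥ neither) emerges as ties within fold-to-fold
spread plus a consistent deficit for the variant with neither branch; the
suite asserts the ordering with a tolerance of the fold sd (floor 0.02).

## Numerical and protocol choices

- Training runs in the tests and acceptance script use grid 32, the
  `tiny` CNN, emb_dim 32, hidden 512/256, 120 epochs, full-batch Adam at
  lr 3e−3 — sizes chosen so a training run takes tens of seconds on one
  CPU core.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; training is bit-reproducible given the seed.
- The autodiff core (`combosyn.nn`) implements exactly the primitives the
  model needs (broadcasted arithmetic, matmul, rectifiers, reductions,
  gather, concatenation, im2col convolution) with reverse-mode gradients
  validated against finite differences; softmax/log-softmax are
  max-shifted for stability; attention masking adds −1e30 to non-edges
  before the softmax.
- Checkpoints store every parameter plus batch-norm running statistics
  in a single NPZ container with a JSON metadata entry (`version: 1`).
- Degenerate inputs: zero-variance expression halves get the bandwidth
  floor; a degenerate grid axis, odd-length vectors, empty molecules,
  single-class training sets and n < k folds all raise immediately with
  specific messages.

## Known limitations

- The full-scale preset (`resnet54-paper`, emb 100, hidden 1024/512) is
  implemented and shape-tested but not trained in the test suite; CPU
  training at that scale is impractical.
- Hyperparameter sweeps (layer count, embedding size, epochs, batch size)
  are exposed through `TrainConfig` but no sweep harness re-runs them.
- Bond orders are deliberately absent from the adjacency (binary by
  definition here); order-aware edges would be a model change, not a
  configuration.
- t-SNE visualization of learned embeddings is out of scope; the
  `render_dkpe_image` utility covers only the density-map figures.
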