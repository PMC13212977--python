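# Methods

## Overview

`gcnpath` predicts drug response — the natural log of the half-maximal
inhibitory concentration, ln(IC50 µM) — for (cell line, compound) pairs.
Cell lines enter the model not as gene expression vectors but as **pathway
crosstalk network (PCN) graphs**: a fixed directed graph over pathways whose
node features are per-sample pathway activity scores.  Compounds enter as
featurized atom–bond graphs parsed from SMILES.  A relation-typed graph
convolutional encoder (cell side) and a multi-head graph attention encoder
(drug side) produce embeddings that a fully connected head combines into a
scalar prediction.

## Pathway activity scoring

Expression is normalized (default `log2(TPM + 1)`) and summarized per sample
into pathway scores.  Three scorers sit behind one interface:

* **gsva / ssgsea** — delegated to `gseapy`'s implementations;
* **singscore** — implemented directly: genes are ranked 1..N per sample
  (average ranks on ties); for a set of n genes with mean rank m the score is
  the min–max normalized mean rank centered at zero,
  `(m − (n+1)/2)/(N − n) − 0.5`, with range [−0.5, +0.5].

Rank-based scorers are invariant under any strictly monotone per-sample
transform of expression — the property that absorbs monotone cross-platform
batch distortions (see *Batch effects* below).

Scores are standardized per pathway by a robust scaler (median center, IQR
scale, linear-interpolation quantiles) fitted on training samples only, and
clamped to |z| ≤ 10.  Pathways with zero IQR get scale 1.0 rather than being
dropped, so the pathway order stays aligned with the PCN node order.

## PCN construction

Two gene-level networks (a PPI network and a regulatory network, both
treated as undirected for distance purposes) are compressed to pathway level
with the **network separation score**

    s_AB = <d_AB> − (<d_AA> + <d_BB>) / 2

where the d-terms are mean shortest-path distances between/within the two
gene sets.  The mean convention is configurable:

* `nearest` (default) — each gene contributes its distance to the closest
  gene of the other set (cross term) or the closest *other* member of its
  own set (within term), following the disease-module separation literature
  from which the score originates;
* `all_pairs` — the plain mean over all gene pairs.

Singleton sets have within-distance 0.  If any required distance is
infinite (disconnected sets), the score is undefined and the pair is
excluded from neighbor ranking.  Genes absent from the network are silently
dropped from the sets first.

Each pathway keeps directed edges to its K = 5 closest neighbors per
relation: lowest separation for the two network relations, highest Pearson
correlation of activity scores for the third.  When fewer than K separation
scores are defined, the shortfall is filled by the highest gene-overlap
(Jaccard) ratios.  Ties break lexicographically by pathway id so builds are
deterministic.  Because neighbor selection is per-source, A→B does not imply
B→A: the PCN is genuinely directed.

A degree-preserving perturbation (`perturb_pcn`) rewires each relation with
double-edge swaps — out- and in-degree multisets preserved exactly, no
self-loops or duplicates — for topology-ablation experiments.

## Drug graphs

RDKit parses SMILES with implicit hydrogens; salts/fragments are kept.  The
feature layout is declarative (`FeatureScheme`): ordered one-hot blocks plus
scalar slots.  The shipped default is 85 atom features (atom type 50,
degree 11, formal charge 6, hybridization 6, chirality 4, H-count 5,
aromaticity, ring membership, mass/100) and 10 bond features (bond type 4,
conjugation, ring, stereo 4).  Downstream model configs assume these
default widths, so alternative layouts load from JSON and non-default
widths are flagged with a warning.
Every chemical bond is stored as two directed edges.  Morgan fingerprints
(128–1024 bits, radius 1–3) are available as the non-graph ablation baseline.

## Model

All tensor computation runs on a small reverse-mode autodiff core
(`gcnpath.nn`) written on numpy; backpropagation is validated against
central finite differences in the test suite (1e-4 relative tolerance on a
sampled 20-parameter subset).

* **Cell encoder** — three relation-typed graph convolution layers
  (relation-specific weight matrices for ppi/grn/corr plus a self term that
  doubles as an implicit self-loop so isolated nodes update; mean
  aggregation over in-neighbors).  DenseGCN wiring: layer i consumes the
  concatenation of the raw score and all previous outputs.  Per-pathway
  outputs of the three layers are concatenated (8+8+8 = 24 channels by
  default) and the whole pathways×24 block is **flattened** — pathway
  identity is preserved rather than pooled away — then projected to the cell
  embedding (256 by default).
* **Drug encoder** — three graph attention layers (4 heads by default) with
  the same dense wiring.  Attention logits use source, target and bond-
  feature projections with LeakyReLU(0.2); head outputs are concatenated and
  projected back to the layer width, which is what keeps the stated hidden
  widths exact.  Self-loops with zero bond features are added internally.
  Atom embeddings are reduced by global max pooling and projected to the
  drug embedding.  Under the default widths [128, 128, 128] the per-atom
  concatenation is sum(drug_hidden) = 384; all layer widths are
  config-driven, so alternative final dimensions are producible.
* **Head** — the 512-dimensional fused embedding passes through two fully
  connected layers (ReLU between, dropout 0.2 during training) to a scalar.

Unstated training choices fixed as defaults: Adam, MSE loss, ELU between
graph layers, ReLU in the head and after each encoder projection, batch 256.
Learning rate is 1e-4 at full scale and 1e-3 in the desk-scale
preset.  Training caps at 300 epochs with early stopping (patience 10) on
validation MSE; the returned state is the best-validation one.  All
randomness (weight init, batch order, dropout) derives from the config seed;
eval-mode predictions are deterministic and serialization round-trips
bit-exactly through `.npz` checkpoints.

### Grad-CAM attribution

For a (cell, drug) pair the attribution reads the first cell-layer
activations A (pathways × channels) and their gradients ∂y_t/∂A obtained by
backpropagation.  Two combining rules are provided:

* `elementwise` (default) — importance_p = ReLU(Σ_k ∂y_t/∂A[p,k]·A[p,k]),
  gradient × activation per pathway;
* `channel_mean` — the canonical Grad-CAM form: α_k = mean_p ∂y_t/∂A[p,k],
  importance_p = ReLU(Σ_k α_k A[p,k]).

The channel-mean form is canonical for architectures whose head shares
weights across positions (global pooling).  This cell encoder instead
*flattens* pathway embeddings through pathway-specific head weights, so
pathway-averaging the gradients discards exactly the per-pathway credit the
head assigns and leaves a residual channel direction that depends on the
random initialization: across training seeds the channel-mean variant's
causal-pathway recovery on the synthetic world swings widely at identical
predictive accuracy, while gradient × activation is stable and markedly
higher.  Both are exposed; the element-wise rule is the default because it
is the faithful analog of Grad-CAM for a flatten head.

The attribution target is also configurable: `sensitivity` (default)
backprops the *negative* prediction, so ReLU retains pathways pushing the
prediction toward drug response — the meaningful direction when explaining
why a pair is sensitive; `response` uses the raw prediction and highlights
resistance-driving pathways.

## Evaluation scenarios

* **unblinded** — pairs split into 10 parts by dealing each cell's pairs
  round-robin (per-cell balance within ±1, approximate per-drug balance);
  fold f tests on part f, validates on part f+1, trains on the rest (8:1:1).
* **cell_blind / drug_blind** — the entity set is split into 10 parts the
  same way; pairs follow their entity.
* **strict_blind** — cells and drugs each split into 5 parts; fold (i, j)
  tests on block (i, j), validates on the cyclically next block
  (i+1, j+1), and trains on the remaining 3×3 blocks (3:1:1 per axis,
  25 folds).  Pairs crossing blind boundaries are discarded from that fold.

Metrics: RMSE, Pearson and Spearman correlations, overall and per
cell/drug (groups need ≥ 3 pairs; rank correlation is meaningless below
that).  Model comparison: one-tailed Mann–Whitney over fold replicates,
exact for combined n ≤ 20 without ties, tie-corrected normal approximation
otherwise; two identical constant samples return 0.5 by convention.
Responder analysis reports mean(responders) − mean(non-responders) as the
effect size with a one-tailed test that responders score lower.  Per-entity
factor statistics: count, mean, sample SD, Sarle's bimodality coefficient
(small-sample corrected, from unbiased skewness and excess kurtosis) and
density coverage — the overlap coefficient between the entity's Gaussian
KDE and the global KDE (Silverman bandwidth, common grid); entities with
n < 4 report these as undefined.

## Synthetic world

The generator produces a complete, self-contained study: a Barabási–Albert
gene network (m = 3); pathways sampled as connected BFS neighborhoods
(12–28 genes) so separation scores are informative, with a configurable
seed-inside-existing-pathway probability controlling overlap (a
`scrambled_pathways` switch produces the topology-free null); latent
pathway activities with a 5-factor low-rank correlation structure and unit
marginals; log-normal TPM-like expression `exp(γ_b·(baseline + loading·
activity) + δ_g + ε)`; and responses
`ln IC50(c,d) = µ_d + Σ_p β_{d,p}·activity_{p,c} + noise` with each drug's
β sparse (1–3 causal pathways).  A `tanh` response link is available for
nonlinearity robustness checks.  Drugs are drawn from a bundled vocabulary
of ~640 valid, synthetic reagent-like SMILES strings shipped in the package
(no downloads).

Two modeling choices deserve emphasis:

* **Batch effects** are a per-batch monotone compression of log expression
  (γ ∈ [0.55, 0.75], the dominant dynamic-range difference between
  platforms) plus independent per-gene offsets (probe effects, SD 0.4) and
  replicate noise (SD 0.1).  Rank scorers are exactly invariant to the
  monotone component; per-batch gene standardization removes per-gene affine
  components; per-sample standardization removes neither per-gene term.
  A world with only per-gene offsets would be the worst case for rank
  methods and does not resemble cross-platform data.
* **Drug-effect signs** are predominantly sensitizing (β < 0 with
  probability 0.8): cells with high activity of a drug's target pathway
  respond at lower concentrations, the oncogene-addiction premise that also
  underlies pathway-attribution case studies; the remainder model
  resistance pathways.  A sign-symmetric world makes channel-averaged
  Grad-CAM attribution directionally ambiguous by construction.

What the world does **not** emulate: count-level noise models, realistic
pathway biology or sizes, any relation between a compound's chemistry and
its causal pathways, dose–response curve shapes, or missing-data structure.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it assumes — not performance on real pharmacogenomic
screens.

### Batch-distortion measure

Distances in different feature spaces (genes vs pathways) are not
commensurable, so the batch comparison uses a scale-free ratio per
representation: mean within-cell cross-batch Euclidean distance divided by
mean between-cell within-batch distance.  This measures batch distortion
relative to the biological separation the representation offers a model,
and is the quantity the batch-effect tests bound (< 25% of the unnormalized
representation's ratio for rank scores and per-batch z-gene; weaker for
z-sample).

## Desk-scale study conditions

The end-to-end tests and the reproduction script run one outer fold per
scenario on a world of 200 cells, 30 pathways (K = 5), 50 drugs and ~5000
pairs at response noise 0.3, with model widths scaled to the 30-pathway
world: drug hidden [32, 32, 32] with 2 heads, 64-dimensional embeddings,
learning rate 1e-3; cell hidden stays at the standard [8, 8, 8].  Checks:
unblinded test RMSE ≤ 0.8 × response SD; cell-blind RMSE below the
train-mean baseline; strict-blind RMSE ≥ unblinded (the difficulty
ordering); top-5 sensitivity attribution hits ≥ 1 causal pathway for ≥ 60%
of sampled sensitive pairs (pairs with the lowest drug-centered responses —
subtracting the drug's own mean isolates the pathway-driven component that
cell features can explain).

## Numerical notes and limitations

* Quantiles use linear interpolation; singscore ties use average ranks;
  KNN ties break lexicographically.
* Max pooling routes gradients to the first attaining row per column.
* Atom-permuted SMILES give embeddings identical up to float summation
  order (~1e-15 relative); byte-identity holds only for identical input
  order.
* The exact Mann–Whitney swap identity is p_swapped = 1 − p + P(U = u_obs);
  the point mass matters at these replicate counts.
* The separation-score MISSING rule makes scores undefined for disconnected
  set pairs; fallback filling is by gene overlap only, so a pathway pair can
  be connected in the PCN without a defined separation score.
* GSVA-style scorers are population-relative: scoring few or strongly
  biased samples against a scaler fitted elsewhere degrades — the same
  caveat that applies to the method on real single-cohort data.
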