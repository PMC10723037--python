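# gtbind

Residue-level protein binding-site prediction with an edge-aware graph
transformer over predicted structures.

## The problem

Which residues of a protein bind a partner — a peptide, another protein, a
nucleic acid?  Binding residues are conserved in the three-dimensional
structure far more than in the sequence, so a predictor that only sees
sequence context misses the spatial patches that form an interface.
`gtbind` treats the task as node classification on a protein graph: each
residue is a node at its Cα position, connected to its k = 30 spatially
nearest residues, and a graph transformer aggregates neighbour features
through geometry-aware attention to score every residue with a binding
probability.

## The model

For a chain with residues *i = 1..n* at Cα positions *x_i*:

* **Node features** `H ∈ R^{n×d}` concatenate a per-residue language-model
  embedding block (min–max normalized to [0, 1] with statistics fitted on
  the training set) and a 14-dimensional structural group: relative solvent
  accessibility, a 9-way secondary-structure one-hot (8 DSSP states + an
  explicit "unassigned"), and sin/cos of the backbone torsions φ, ψ.
* **Local frames** `O_i = [b_i, n_i, b_i × n_i]`, where `b_i` is the
  negative bisector of the angle between the virtual bonds into and out of
  residue *i* and `n_i` its plane normal.
* **Edge features** for each directed edge *j → i*:
  16 Gaussian RBF activations of the distance ‖x_j − x_i‖ (centers on
  [0, 20] Å), the unit direction `O_iᵀ(x_j − x_i)/‖x_j − x_i‖`, the unit
  quaternion of the relative rotation `O_iᵀO_j`, and a sinusoidal encoding
  of the signed sequence gap *j − i*.  All of these are invariant under
  rotation and translation of the structure.
* **Edge-aware attention** per head:
  `score(i, j) = (W_Q h_i)ᵀ(W_K [h_j ‖ e_ij]) / √d_h`, softmax over
  `j ∈ N_i ∪ {i}`, message `Σ_j α_ij [W_V h_j ‖ e_ij]`, heads concatenated
  and projected back to d with a residual, followed by a position-wise
  feed-forward block.  Four layers, four heads, 64 hidden units, dropout
  0.2 by default.
* **Head** `Y′ = sigmoid(H_L W + b)` — one binding probability per residue.

Training minimizes residue-level binary cross-entropy with Adam
(β₁ = 0.9, β₂ = 0.98, ε = 1e-9), resampling proteins with replacement each
epoch, Gaussian feature-noise augmentation, early stopping on validation
AUPRC, 5-fold cross-validation at the protein level, and prediction by
ensemble averaging.  Evaluation reports accuracy, precision, recall,
specificity, F1, and MCC at the MCC-maximizing threshold, plus AUC and
AUPRC, optionally stratified by each residue's number of nonlocal contacts
(sequence separation > 20, Cα distance < 12 Å).

The network and its gradients are implemented directly in NumPy (float64);
analytic backpropagation is verified against finite differences in the
test suite.

## Worked example

Everything runs end to end on synthetic fixtures — compact self-avoiding
Cα walks with spatially planted binding labels and embeddings carrying a
controllable signal — written in the same on-disk layout real data uses
(one PDB per protein, an embedding container, a label TSV):

```bash
# from an empty working directory (paths in the configs are relative)
cp <repo>/examples/*.yaml .
gtbind make-fixtures fixtures.yaml   # writes data/
gtbind train train.yaml              # writes ckpt/fold*.npz + CV report
gtbind predict predict.yaml          # writes pred/<id>.tsv
gtbind evaluate evaluate.yaml        # writes report/metrics.txt + stratified.tsv
```

With the shipped example configs (20 proteins of 30–60 residues,
protein-like class balance PNratio 0.18, a reduced 2-layer/32-unit
network, 2-fold CV, 12 epochs, seed 1) the train step prints:

```
Cross-validation summary
  folds: 2   monitor: auprc
  ensemble threshold (median of folds): 0.1466
  fold  best_epoch  val_auprc  val_auc
     0          12     0.5371   0.8291
     1          12     0.3208   0.7468
  val auprc: mean 0.4289 +/- sd 0.1530
  val auc: mean 0.7880 +/- sd 0.0582
```

and the evaluate step writes `report/metrics.txt`:

```
threshold_provenance	max-MCC on these labels
TP	74
TN	712
FP	27
FN	54
ACC	0.9065743944636678
Pre	0.7326732673267327
Rec	0.578125
Spe	0.9634641407307172
F1	0.646288209606987
MCC	0.598855551842539
AUC	0.8931199255751014
AUPRC	0.6974023025998284
threshold	0.160939
degenerate	-
```

Reading this: of the 867 residues, 128 are binding (prevalence ≈ 0.15);
at the MCC-maximizing threshold 0.161 the ensemble recovers 74 of them at
precision 0.73, for an MCC of 0.60 and an AUPRC of 0.70 — far above the
0.15 a chance predictor would score.  Every validation AUPRC/AUC in the
CV summary is computed on proteins the fold's model never saw.  Numbers
are exactly reproducible for a fixed seed.

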