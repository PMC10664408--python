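# gdec

Graph-based deep embedded clustering with transfer learning for single-cell
RNA-seq.

Cell-type clustering of scRNA-seq data is hard because the cells × genes
count matrix is sparse, high-dimensional and noisy, and because most
clustering tools look only at the target dataset, ignoring the well-annotated
("gold standard") atlases that already exist for other species and batches.
`gdec` addresses both problems:

* **Gene-graph embeddings.** A two-layer graph convolution over a
  gene-interaction network learns a per-gene embedding matrix *M* ∈ ℝ^{g×d}.
  Each layer aggregates neighbours with symmetric degree normalisation,

  h_i^{(l+1)} = σ( b^{(l)} + Σ_{j∈N(i)} h_j^{(l)} W^{(l)} / (√deg(j)·√deg(i)) ),

  trained self-supervised on link prediction. The expression profile
  *S* ∈ ℝ^{a×g} is fused with the embeddings as *D = S·M* and the DEC input is
  the concatenation *I = [S, D]* (or *[S, D′]* with *D′* the row sums of *D*).

* **Deep embedded clustering (DEC).** A mirrored autoencoder
  (input → 500 → 500 → 2000 → 20) is pretrained on reconstruction; K-means on
  the 20-d embedding initialises centroids μ_j; soft assignments use a
  Student's-t kernel,

  q_ij ∝ (1 + ‖z_i − μ_j‖²/α)^{−(α+1)/2},

  and self-training minimises KL(P‖Q) against the sharpened target
  p_ij ∝ q_ij²/f_j with f_j = Σ_i q_ij.

* **Transfer with open-set rejection.** The model pretrained on a labelled
  source dataset is transferred to a target dataset from another species or
  batch and fine-tuned, optionally with a small labelled fraction of target
  cells as prior knowledge. Cells whose maximum soft assignment stays below a
  threshold τ are reported as `"unknown"` instead of being forced into a
  known type — novel cell types surface as rejected groups.

Everything is testable end-to-end on seeded synthetic data: the
`gdec.simulate` module generates planted-cluster count matrices with dropout,
source/target pairs with per-gene multiplicative batch effects and held-out
cell types, and planted-partition gene graphs.

## Worked example

```python
from gdec import (GDEC, GdecConfig, SimulationConfig, TransferConfig,
                  simulate_pair, simulate_gene_graph)
from gdec.simulate import sample_prior_labels

cfg = SimulationConfig(seed=1)              # 800 cells, 200 genes, 4 types
(src, src_lab), (tgt, tgt_lab) = simulate_pair(cfg)
graph = simulate_gene_graph(cfg)

model = GDEC(src, graph, src_lab, GdecConfig.compact())
results = model.fit(seed=1)
print(results.summary())

prior = sample_prior_labels(tgt_lab, 0.1, seed=101)   # 10% labelled target cells
transfer = results.transfer(tgt, prior, TransferConfig(seed=1))
print(transfer.evaluate(tgt_lab))
```

Output:

```
GDEC source model
==============================================
cells: 800    genes: 80
clusters (k): 4    alpha: 1.0
encoder: 81 -> 128 -> 128 -> 512 -> 20
gene embedding: d=16
final pretrain MSE: 3.21068
final KL(P||Q): 87.96609
training accuracy (Hungarian): 0.9938
----------------------------------------------
cluster  size  mapped type
      0   201  type2
      1   198  type1
      2   201  type0
      3   200  type3
{'accuracy': 1.0, 'ari': 0.8514858343462625, 'nmi': 0.8443889600957892}
```

The summary reports the fitted source model: 800 cells over the 80 most
variable of 200 genes (plus one fused gene-interaction column, hence encoder
input 81), four clusters each mapped to its majority source type, and 99.38%
Hungarian-matched training accuracy. After transfer and fine-tuning with 10%
prior labels, every confidently assigned target cell lands on its correct
type despite the injected batch effect (accuracy 1.0 on this seed); ARI/NMI
are lower because the cells rejected at τ = 0.6 count as their own
`"unknown"` group in those partition metrics.

The same pipeline is available from the shell:

```bash
gdec simulate --n-cells 800 --k-types 4 --seed 1 --outdir sim/
gdec pretrain-source --expr sim/source.mtx --labels sim/source.labels.tsv \
     --graph sim/graph.tsv --seed 1 --out model.npz
gdec transfer --bundle model.npz --target sim/target.mtx \
     --prior sim/target.labels.tsv --tau 0.6 --out assignments.tsv
gdec evaluate --true sim/target.labels.tsv --pred assignments.tsv --out report.json
```

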