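# epimci

Hypergraph-neural-network prediction of multi-way chromatin interactions from
epigenomic signals, with two downstream applications: likelihood-based
denoising of pairwise contact matrices and compartment-level analysis of the
learned bin embeddings.

A multi-way contact read (e.g. from Pore-C/HiPore-C) is binned into a set of
fixed-width genome bins; co-occurring bin sets become hyperedges of a
genome-wide hypergraph. The scorer combines two channels per candidate
hyperedge:

* a **separating** channel that looks only at the tuple itself — masked
  multi-head self-attention over the member bins' feature embeddings plus a
  per-vertex MLP, aligned by a KL loss;
* a **coupling** channel that propagates bin features through the positive
  hypergraph with symmetric-normalized hypergraph convolutions.

The two are fused per vertex, scored with a sigmoid head, and averaged into
the probability that the bin set forms a real multi-way interaction. Bin
features are per-bin peak counts from BED/narrowPeak tracks, compressed by a
stacked autoencoder (widths 128 → 64). Negatives are built by replacing
zero-truncated-binomial-many vertices of each positive within a ±20-bin
window, so negatives match positives in 1D-distance profile.

Everything runs on numpy: the package ships a small reverse-mode autodiff
engine (`epimci.autograd`) and an Adam optimizer, so no deep-learning
framework is required. A bundled simulator generates genomes, compartment
labels, multi-way reads and peak tracks with planted structure, so the whole
pipeline is testable offline.

## Command line

All coordinates are 0-based, half-open. A full synthetic run:

```bash
epimci simulate --out data                        # chrom.sizes, labels, clusters, BED tracks
epimci build --clusters data/clusters.txt \
    --chrom-sizes data/chrom.sizes \
    --thresholds 3:53,4:33,5:16,6:5 --out edges.tsv
epimci sample-negatives --edges edges.tsv \
    --chrom-sizes data/chrom.sizes --ratio 2 --p 0.5 --window 20 \
    --seed 1 --out samples.tsv
epimci features --beds data/tracks --chrom-sizes data/chrom.sizes --out features.tsv
epimci encode --features features.tsv --widths 128,64 --epochs 200 --seed 1 --out emb.tsv
epimci train --samples samples.tsv --embeddings emb.tsv --edges edges.tsv \
    --seed 1 --out model.ckpt --report report.json
epimci evaluate --model model.ckpt --samples samples.tsv \
    --embeddings emb.tsv --edges edges.tsv
epimci denoise --model model.ckpt --contacts contacts.txt \
    --chrom-sizes data/chrom.sizes --embeddings emb.tsv --edges edges.tsv \
    --out denoised.txt
epimci embed --model model.ckpt --embeddings emb.tsv --edges edges.tsv \
    --labels data/labels.tsv --out fused.tsv
epimci grid --samples samples.tsv --embeddings emb.tsv --out grid.json
```

`epimci train` accepts a TOML config overriding batch size (default 96),
dropout (0.4), learning rate (1e-3), epochs (200), the KL loss weight, and
the ablation variant (`full`, `noSHE` = structural channel only, `noCHE` =
separating channel only). Training is five-fold-CV-ready
(`epimci.training.cross_validate`), stratified by label and hyperedge order,
and the coupling-channel incidence matrix is always rebuilt from the training
fold's positives only.

## Library

```python
from epimci import SyntheticSpec, TrainConfig, pipeline

data = pipeline.prepare_synthetic(SyntheticSpec(seed=1))
fold = pipeline.train_heldout(data, TrainConfig(epochs=20, seed=1))
print(fold.report.overall)  # auc, aupr, accuracy, precision, recall, f1
```

One module per stage: `genome_io` (chrom.sizes, cluster files, COO contact
matrices), `synthetic` (simulator), `hypergraph` (binning, decomposition,
frequency filtering, incidence/degree matrices), `sampling` (negative
construction), `features` (peak counting, stacked autoencoder), `model` (the
dual-channel scorer), `training` (CV, metrics, grid search), `applications`
(denoising, PCA compartment analysis).

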