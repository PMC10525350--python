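"""One-call orchestration of the synthetic end-to-end pipeline.

Chains the simulator, hypergraph construction, negative sampling, feature
encoding and model training through their public interfaces, writing and
re-reading every on-disk artifact so the file formats are exercised too.
Used by the test suite and the acceptance report, and handy as a worked
example of the API.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import features, hypergraph, sampling, synthetic, training
from .genome_io import GenomeBins, MultiwayRead, read_chrom_sizes, read_cluster_file
from .hypergraph import Hypergraph, HyperedgeSet
from .model import ModelConfig, ModelParams
from .sampling import LabeledSample
from .training import MetricsReport, TrainConfig


@dataclass
class PreparedData:
    """Everything the trainer needs, derived from one synthetic spec."""

    spec: synthetic.SyntheticSpec
    bins: GenomeBins
    labels: np.ndarray
    reads: list[MultiwayRead]
    positives: HyperedgeSet
    samples: list[LabeledSample]
    embeddings: np.ndarray


@dataclass
class TrainedFold:
    params: ModelParams
    graph: Hypergraph
    report: MetricsReport
    test_samples: list[LabeledSample]


def prepare_synthetic(
    spec: synthetic.SyntheticSpec,
    thresholds: dict[int, int] | None = None,
    sae_epochs: int = 200,
    workdir: str | Path | None = None,
) -> PreparedData:
    """Simulate, construct hyperedges, sample negatives and encode features.

    All artifacts are round-tripped through their text formats under
    ``workdir`` (a temporary directory by default).
    """
    if thresholds is None:
        thresholds = dict(hypergraph.DEFAULT_THRESHOLDS)
    with tempfile.TemporaryDirectory() as tmp:
        outdir = Path(workdir) if workdir is not None else Path(tmp)
        paths = synthetic.simulate_dataset(spec, outdir)
        bins = read_chrom_sizes(paths["chrom_sizes"], spec.bin_size)
        labels = synthetic.read_labels(paths["labels"])
        reads = list(read_cluster_file(paths["clusters"]))
        counts = hypergraph.count_hyperedges(reads, bins)
        positives = hypergraph.count_and_filter(counts, thresholds, bins.n_bins)
        samples = sampling.build_dataset(positives, bins, seed=spec.seed)
        bed_paths = sorted((outdir / "tracks").glob("*.bed"))
        table = features.build_feature_table(bed_paths, bins)
        sae = features.train_sae(table, epochs=sae_epochs, seed=spec.seed)
        embeddings = features.encode(sae, table)
    return PreparedData(spec, bins, labels, reads, positives, samples, embeddings)


def train_heldout(
    data: PreparedData,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    fold: int = 0,
) -> TrainedFold:
    """Train on one CV fold's training split, evaluate on its held-out split.

    The coupling-channel hypergraph is built from the training split's
    positives only.
    """
    splits = training.kfold_split(data.samples, config.folds, config.seed)
    train_idx, test_idx = splits[fold]
    train_set = [data.samples[i] for i in train_idx]
    test_set = [data.samples[i] for i in test_idx]
    graph = training.graph_from_samples(train_set, data.bins.n_bins)
    result = training.train(train_set, data.embeddings, graph, config, model_config)
    report = training.evaluate(result.params, test_set, data.embeddings, graph)
    report.loss_curve = result.report.loss_curve
    report.val_loss_curve = result.report.val_loss_curve
    return TrainedFold(result.params, graph, report, test_set)


def noise_injected_contacts(
    data: PreparedData, noise_fraction: float = 0.3, noise_seed_offset: int = 10_000
) -> tuple:
    """Clean and noise-injected pairwise contact matrices for denoising runs.

    The clean matrix decomposes the prepared reads; the noisy one adds
    ``noise_fraction`` x n_reads uniformly random reads (an intra-compartment
    bias of zero) drawn with a shifted seed.
    """
    clean = hypergraph.contacts_from_reads(data.reads, data.bins)
    noise_spec = replace(
        data.spec,
        intra_compartment_bias=0.0,
        n_reads=int(noise_fraction * data.spec.n_reads),
        seed=data.spec.seed + noise_seed_offset,
    )
    noise_reads = synthetic.simulate_multiway_reads(data.bins, data.labels, noise_spec)
    noisy = hypergraph.contacts_from_reads(data.reads + noise_reads, data.bins)
    return clean, noisy
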