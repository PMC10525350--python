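"""Synthetic genomes, compartment labels, multi-way reads and peak tracks.

Everything downstream (hypergraph construction, negative sampling, features,
the model) is testable on this generator alone: it plants alternating A/B
compartment blocks of geometric length, draws multi-way reads that are
biased to stay inside a single compartment block, and emits per-track peak
counts whose Poisson means differ between the A and B labels.

All randomness derives from ``SyntheticSpec.seed``; identical specs produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    GenomeBins,
    MultiwayRead,
    ValidationError,
    write_chrom_sizes,
    write_cluster_file,
)

#: Default distribution over read orders 2..8: concentrated on 3-6 with a
#: tail at 7-8 to exercise decomposition of higher-order contacts.
DEFAULT_ORDER_DISTRIBUTION: dict[int, float] = {
    2: 0.02,
    3: 0.08,
    4: 0.15,
    5: 0.30,
    6: 0.30,
    7: 0.10,
    8: 0.05,
}

#: Mean compartment-block length in bins (geometric).
MEAN_BLOCK_LENGTH = 10

_FRAGMENT_WIDTH = 100
_PEAK_WIDTH = 200


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dataset."""

    n_chroms: int = 3
    bins_per_chrom: int = 200
    n_reads: int = 20_000
    order_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ORDER_DISTRIBUTION)
    )
    intra_compartment_bias: float = 0.8
    n_tracks: int = 8
    signal_effect: float = 4.0
    baseline_rate: float = 1.0
    bin_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.intra_compartment_bias <= 1.0:
            raise ValidationError("intra_compartment_bias must be in [0, 1]")
        for name in ("n_chroms", "bins_per_chrom", "n_tracks"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_reads < 0:
            raise ValidationError("n_reads must be non-negative")
        total = sum(self.order_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"order_distribution sums to {total}, expected 1")
        if any(k < 2 or p < 0 for k, p in self.order_distribution.items()):
            raise ValidationError("order_distribution keys must be >= 2 with p >= 0")


def _rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stage]))


def simulate_genome(spec: SyntheticSpec) -> tuple[GenomeBins, np.ndarray]:
    """Generate a genome and per-bin compartment labels.

    Labels are assigned in contiguous blocks of geometric length (mean
    ``MEAN_BLOCK_LENGTH`` bins) alternating between A and B within each
    chromosome; the starting label of each chromosome is random.
    """
    names = tuple(f"chr{i + 1}" for i in range(spec.n_chroms))
    sizes = tuple(spec.bins_per_chrom * spec.bin_size for _ in range(spec.n_chroms))
    bins = GenomeBins(names, sizes, spec.bin_size)
    rng = _rng(spec, 0)
    labels = np.empty(bins.n_bins, dtype="<U1")
    pos = 0
    for _ in range(spec.n_chroms):
        current = "A" if rng.random() < 0.5 else "B"
        remaining = spec.bins_per_chrom
        while remaining > 0:
            length = min(int(rng.geometric(1.0 / MEAN_BLOCK_LENGTH)), remaining)
            labels[pos : pos + length] = current
            pos += length
            remaining -= length
            current = "B" if current == "A" else "A"
    return bins, labels


def compartment_blocks(labels: np.ndarray) -> list[np.ndarray]:
    """Contiguous runs of equal label, as arrays of global bin indices."""
    labels = np.asarray(labels)
    boundaries = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return [np.arange(s, e) for s, e in zip([0, *boundaries], [*boundaries, len(labels)])]


def _genome_blocks(bins: GenomeBins, labels: np.ndarray) -> list[np.ndarray]:
    """Label blocks split at chromosome boundaries."""
    blocks: list[np.ndarray] = []
    per_chrom = bins.bins_per_chrom()
    start = 0
    for count in per_chrom:
        for block in compartment_blocks(labels[start : start + count]):
            blocks.append(block + start)
        start += count
    return blocks


def _bin_fragment(bins: GenomeBins, index: int) -> tuple[str, int, int]:
    chrom, start, end = bins.bin_interval(index)
    mid = (start + end) // 2
    return chrom, mid, min(mid + _FRAGMENT_WIDTH, end)


def simulate_multiway_reads(
    bins: GenomeBins, labels: np.ndarray, spec: SyntheticSpec
) -> list[MultiwayRead]:
    """Draw multi-way reads with planted compartment structure.

    For each read an order ``k`` is drawn from ``spec.order_distribution``.
    With probability ``intra_compartment_bias`` all ``k`` bins are drawn
    uniformly (without replacement) from a single compartment block — chosen
    with probability proportional to its size among blocks holding at least
    ``k`` bins — otherwise uniformly from all bins. Bins are emitted as
    fragments at the bin midpoint.
    """
    if len(labels) != bins.n_bins:
        raise ValidationError("labels length must equal n_bins")
    rng = _rng(spec, 1)
    orders = np.array(sorted(spec.order_distribution), dtype=int)
    probs = np.array([spec.order_distribution[k] for k in orders], dtype=float)
    probs = probs / probs.sum()
    blocks = _genome_blocks(bins, labels)
    block_sizes = np.array([len(b) for b in blocks])
    all_bins = np.arange(bins.n_bins)
    reads: list[MultiwayRead] = []
    ks = rng.choice(orders, size=spec.n_reads, p=probs)
    for i in range(spec.n_reads):
        k = int(ks[i])
        while k > bins.n_bins:  # degenerate genome: resample the order
            k = int(rng.choice(orders, p=probs))
        if rng.random() < spec.intra_compartment_bias:
            eligible = np.flatnonzero(block_sizes >= k)
            if eligible.size > 0:
                weights = block_sizes[eligible] / block_sizes[eligible].sum()
                block = blocks[int(rng.choice(eligible, p=weights))]
                chosen = rng.choice(block, size=k, replace=False)
            else:
                chosen = rng.choice(all_bins, size=k, replace=False)
        else:
            chosen = rng.choice(all_bins, size=k, replace=False)
        fragments = tuple(_bin_fragment(bins, int(g)) for g in sorted(chosen))
        reads.append(MultiwayRead(f"read{i}", fragments))
    return reads


def simulate_peaks(
    bins: GenomeBins, labels: np.ndarray, spec: SyntheticSpec
) -> list[tuple[str, list[tuple[str, int, int]]]]:
    """Generate peak tracks as (track_name, BED interval list) pairs.

    Per track and bin, a peak count is drawn from a Poisson whose mean is
    ``baseline_rate`` for one label and ``baseline_rate + signal_effect`` for
    the other; half of the tracks are "active" (elevated in A), the rest are
    flipped. Peaks are ``_PEAK_WIDTH`` bp intervals placed inside the bin.
    """
    if len(labels) != bins.n_bins:
        raise ValidationError("labels length must equal n_bins")
    rng = _rng(spec, 2)
    is_a = np.asarray(labels) == "A"
    tracks: list[tuple[str, list[tuple[str, int, int]]]] = []
    for t in range(spec.n_tracks):
        active = t < (spec.n_tracks + 1) // 2
        mu_a = spec.baseline_rate + (spec.signal_effect if active else 0.0)
        mu_b = spec.baseline_rate + (0.0 if active else spec.signal_effect)
        means = np.where(is_a, mu_a, mu_b)
        counts = rng.poisson(means)
        intervals: list[tuple[str, int, int]] = []
        for g in np.flatnonzero(counts):
            chrom, start, end = bins.bin_interval(int(g))
            span = max(end - start - _PEAK_WIDTH, 1)
            for offset in rng.integers(0, span, size=int(counts[g])):
                s = start + int(offset)
                intervals.append((chrom, s, min(s + _PEAK_WIDTH, end)))
        tracks.append((f"track{t}", intervals))
    return tracks


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")


def read_labels(path: str | Path) -> np.ndarray:
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            idx, lab = line.split()
            out[int(idx)] = lab
    return np.array([out[i] for i in range(len(out))])


def simulate_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulator and write every artifact under ``outdir``.

    Writes ``chrom.sizes``, ``labels.tsv``, ``clusters.txt`` and one
    ``<track>.bed`` per peak track; returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins, labels = simulate_genome(spec)
    reads = simulate_multiway_reads(bins, labels, spec)
    tracks = simulate_peaks(bins, labels, spec)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "labels": outdir / "labels.tsv",
        "clusters": outdir / "clusters.txt",
    }
    write_chrom_sizes(bins, paths["chrom_sizes"])
    write_labels(labels, paths["labels"])
    write_cluster_file(reads, paths["clusters"])
    beds = outdir / "tracks"
    beds.mkdir(exist_ok=True)
    for name, intervals in tracks:
        path = beds / f"{name}.bed"
        write_bed(intervals, path)
        paths[name] = path
    return paths
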