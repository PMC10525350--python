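"""Negative sampling by zero-truncated-binomial vertex corruption.

Positives are the filtered hyperedges; each negative is produced by drawing
k ~ Binomial(order, p) conditioned on k >= 1 (and redrawn until k < order so
at least one vertex is kept), then replacing k vertices with bins sampled
uniformly from a window of +/- ``window`` bins on the same chromosome. The
window keeps the 1D genomic-distance profile of negatives close to that of
positives, so the two classes cannot be told apart by distance alone.
Corrupted tuples colliding with the positive set are rejected and retried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GenomeBins, ValidationError
from .hypergraph import Hyperedge, HyperedgeSet

logger = logging.getLogger(__name__)

DEFAULT_RATIO = 2
DEFAULT_P = 0.5
DEFAULT_WINDOW = 20
DEFAULT_MAX_RETRIES = 100
MIN_SAMPLE_ORDER = 3


@dataclass(frozen=True)
class LabeledSample:
    """A bin tuple with its hyperedge-membership label (1 positive, 0 negative)."""

    bins: tuple[int, ...]
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")
        if list(self.bins) != sorted(set(self.bins)):
            raise ValidationError(f"sample bins must be sorted and distinct: {self.bins}")

    @property
    def order(self) -> int:
        return len(self.bins)


def truncated_binomial_pmf(order: int, p: float) -> np.ndarray:
    """pmf of Binomial(order, p) conditioned on k >= 1, over k = 1..order."""
    from scipy.stats import binom

    k = np.arange(1, order + 1)
    pmf = binom.pmf(k, order, p)
    return pmf / (1.0 - (1.0 - p) ** order)


def sample_k(order: int, p: float, rng: np.random.Generator) -> int:
    """Draw the number of vertices to replace: Binomial(order, p) | k >= 1."""
    if not 0.0 < p < 1.0:
        raise ValidationError(f"replacement probability must be in (0, 1), got {p}")
    if order < MIN_SAMPLE_ORDER:
        raise ValidationError(f"order must be >= {MIN_SAMPLE_ORDER}, got {order}")
    while True:
        k = int(rng.binomial(order, p))
        if k >= 1:
            return k


class NegativeSamplingError(RuntimeError):
    """Raised when the requested number of negatives cannot be generated."""


def corrupt(
    edge: Hyperedge,
    k: int,
    bins: GenomeBins,
    positives: set[tuple[int, ...]],
    rng: np.random.Generator,
    window: int = DEFAULT_WINDOW,
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> LabeledSample | None:
    """Replace ``k`` vertices of a positive edge to produce one negative.

    Each chosen vertex is replaced by a bin drawn uniformly from within
    +/- ``window`` bins on its own chromosome, excluding bins already in the
    tuple; if the window holds no candidate it widens to the whole
    chromosome. Returns ``None`` (logged) when ``max_retries`` attempts all
    collide with the positive set or fail to produce a valid tuple.
    """
    if not 1 <= k < edge.order:
        raise ValidationError(f"k must satisfy 1 <= k < order, got k={k}, order={edge.order}")
    per_chrom = bins.bins_per_chrom()
    for _ in range(max_retries):
        replaced_at = rng.choice(edge.order, size=k, replace=False)
        new_bins = list(edge.bins)
        ok = True
        for pos in replaced_at:
            v = edge.bins[pos]
            c = bins.chrom_of_bin(v)
            lo = bins.offsets[c]
            hi = lo + per_chrom[c]  # exclusive
            w_lo, w_hi = max(lo, v - window), min(hi, v + window + 1)
            exclude = set(new_bins)
            candidates = [b for b in range(w_lo, w_hi) if b not in exclude]
            if not candidates:  # tiny chromosome: widen to the whole chromosome
                candidates = [b for b in range(lo, hi) if b not in exclude]
            if not candidates:
                ok = False
                break
            new_bins[pos] = int(candidates[int(rng.integers(len(candidates)))])
        if not ok:
            continue
        candidate = tuple(sorted(new_bins))
        if len(candidate) == edge.order and candidate not in positives:
            return LabeledSample(candidate, 0)
    logger.debug("corrupt: exhausted %d retries for edge %s", max_retries, edge.bins)
    return None


def build_dataset(
    positives: HyperedgeSet,
    bins: GenomeBins,
    ratio: int = DEFAULT_RATIO,
    p: float = DEFAULT_P,
    window: int = DEFAULT_WINDOW,
    max_retries: int = DEFAULT_MAX_RETRIES,
    seed: int = 0,
) -> list[LabeledSample]:
    """Build the labeled dataset: every positive plus ``ratio`` negatives each.

    Corruption preserves the order of the source edge, so per-order negative
    counts are proportional to per-order positive counts. When an edge
    exhausts its retries, a different randomly chosen positive is corrupted
    instead so the exact ratio is always met; if that also fails the
    shortfall is reported as an error. The output is shuffled
    deterministically by ``seed`` and negatives never collide with positives.
    """
    if len(positives) == 0:
        raise ValidationError("positives must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    positive_tuples = positives.tuples()
    samples: list[LabeledSample] = [LabeledSample(e.bins, 1) for e in positives]
    edges = list(positives)
    n_target = ratio * len(edges)
    n_made = 0
    skipped = 0
    for edge in edges:
        for _ in range(ratio):
            sample = _corrupt_with_fallback(
                edge, edges, bins, positive_tuples, rng, p, window, max_retries
            )
            if sample is None:
                skipped += 1
                continue
            samples.append(sample)
            n_made += 1
    if n_made < n_target:
        raise NegativeSamplingError(
            f"could not generate enough negatives: {n_made}/{n_target} "
            f"({skipped} edges exhausted retries)"
        )
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def _draw_k(order: int, p: float, rng: np.random.Generator) -> int:
    """sample_k redrawn until k < order (corrupt keeps >= 1 vertex)."""
    while True:
        k = sample_k(order, p, rng)
        if k < order:
            return k


def _corrupt_with_fallback(
    edge: Hyperedge,
    edges: Sequence[Hyperedge],
    bins: GenomeBins,
    positive_tuples: set[tuple[int, ...]],
    rng: np.random.Generator,
    p: float,
    window: int,
    max_retries: int,
    n_fallbacks: int = 20,
) -> LabeledSample | None:
    sample = corrupt(
        edge, _draw_k(edge.order, p, rng), bins, positive_tuples, rng, window, max_retries
    )
    attempts = 0
    while sample is None and attempts < n_fallbacks:
        other = edges[int(rng.integers(len(edges)))]
        sample = corrupt(
            other, _draw_k(other.order, p, rng), bins, positive_tuples, rng, window, max_retries
        )
        attempts += 1
    return sample


def write_samples(samples: Sequence[LabeledSample], path: str | Path) -> None:
    """Samples TSV: ``bins(comma-joined)<TAB>label``."""
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f"{','.join(map(str, s.bins))}\t{s.label}\n")


def read_samples(path: str | Path) -> list[LabeledSample]:
    out: list[LabeledSample] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            bins_txt, label_txt = line.split("\t")
            out.append(LabeledSample(tuple(int(b) for b in bins_txt.split(",")), int(label_txt)))
    return out
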