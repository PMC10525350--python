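"""From multi-way reads to filtered hyperedges and hypergraph matrices.

A read's fragments are midpoint-assigned to genome bins; the resulting bin
set is decomposed into all subsets within an order window (default 3..6),
occurrence frequencies are accumulated across reads, and hyperedges passing
per-order frequency thresholds become the positive set. The positive set is
materialized as a sparse binary incidence matrix ``H`` with diagonal
hyperedge weights ``W``, vertex weights ``U`` (identity), vertex degrees
``Dv[i,i] = sum_e W[e,e] H[i,e]`` and hyperedge degrees
``De[e,e] = sum_i H[i,e]``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp

from .genome_io import ContactMatrix, GenomeBins, MultiwayRead, ValidationError

MIN_ORDER = 3
MAX_ORDER = 6

#: Default per-order frequency thresholds for the bundled synthetic data;
#: chosen (like the per-dataset thresholds of the reference method) to keep
#: the per-order positive counts balanced.
DEFAULT_THRESHOLDS: dict[int, int] = {3: 53, 4: 33, 5: 16, 6: 5}


@dataclass(frozen=True)
class Hyperedge:
    """A filtered positive hyperedge: sorted distinct bins plus its frequency."""

    bins: tuple[int, ...]
    frequency: int

    def __post_init__(self):
        if list(self.bins) != sorted(set(self.bins)):
            raise ValidationError(f"hyperedge bins must be sorted and distinct: {self.bins}")
        if self.frequency < 1:
            raise ValidationError("hyperedge frequency must be >= 1")

    @property
    def order(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class HyperedgeSet:
    """Ordered collection of positive hyperedges over ``n_bins`` vertices."""

    edges: tuple[Hyperedge, ...]
    n_bins: int

    def __post_init__(self):
        for e in self.edges:
            if e.bins[-1] >= self.n_bins:
                raise ValidationError(f"hyperedge {e.bins} exceeds n_bins={self.n_bins}")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[Hyperedge]:
        return iter(self.edges)

    def tuples(self) -> set[tuple[int, ...]]:
        return {e.bins for e in self.edges}


@dataclass
class Hypergraph:
    """Sparse incidence representation with diagonal weight/degree matrices."""

    H: sp.csr_matrix
    W: sp.dia_matrix
    U: sp.dia_matrix
    Dv: sp.dia_matrix
    De: sp.dia_matrix
    n_bins: int = field(init=False)
    n_edges: int = field(init=False)

    def __post_init__(self):
        self.n_bins, self.n_edges = self.H.shape


def bin_read(read: MultiwayRead, bins: GenomeBins) -> tuple[int, ...]:
    """Midpoint-bin a read's fragments into a sorted tuple of distinct bins.

    A fragment spanning a bin boundary belongs to the bin containing its
    midpoint. Duplicate bins collapse, so the tuple can be shorter than the
    fragment list.
    """
    indices = set()
    for chrom, start, end in read.fragments:
        midpoint = (start + end) // 2
        indices.add(bins.global_bin(chrom, midpoint))
    return tuple(sorted(indices))


def decompose(
    bins_tuple: tuple[int, ...],
    min_order: int = MIN_ORDER,
    max_order: int = MAX_ORDER,
) -> Iterator[tuple[int, ...]]:
    """All subsets of ``bins_tuple`` with size in [min_order, max_order].

    Tuples shorter than ``min_order`` yield nothing; a tuple of length k
    yields sum_j C(k, j) subsets for j in the window.
    """
    for j in range(min_order, min(max_order, len(bins_tuple)) + 1):
        yield from combinations(bins_tuple, j)


def count_hyperedges(
    reads: Iterable[MultiwayRead],
    bins: GenomeBins,
    min_order: int = MIN_ORDER,
    max_order: int = MAX_ORDER,
) -> Counter:
    """Accumulate hyperedge frequencies across reads.

    Each read supports a given tuple at most once (subsets are deduplicated
    within a read by construction, since the binned tuple has distinct bins).
    """
    counts: Counter = Counter()
    for read in reads:
        tup = bin_read(read, bins)
        counts.update(decompose(tup, min_order, max_order))
    return counts


def count_and_filter(
    counts: Counter, thresholds: dict[int, int], n_bins: int
) -> HyperedgeSet:
    """Keep tuples with frequency >= the threshold for their order.

    Output ordering is deterministic (lexicographic by bins). ``thresholds``
    must cover every order present in ``counts``.
    """
    orders = {len(t) for t in counts}
    missing = orders - set(thresholds)
    if missing:
        raise ValidationError(f"no threshold defined for orders {sorted(missing)}")
    kept = [
        Hyperedge(tup, freq)
        for tup, freq in counts.items()
        if freq >= thresholds[len(tup)]
    ]
    kept.sort(key=lambda e: e.bins)
    return HyperedgeSet(tuple(kept), n_bins)


def build_hypergraph(
    edges: HyperedgeSet,
    n_bins: int | None = None,
    weight_by_frequency: bool = False,
) -> Hypergraph:
    """Assemble H, W, U, Dv, De from a positive hyperedge set.

    ``W`` defaults to the identity; with ``weight_by_frequency`` each
    hyperedge weight is its frequency divided by the mean frequency. ``U``
    is always the identity (it appears in no propagation rule).
    """
    n = edges.n_bins if n_bins is None else n_bins
    m = len(edges)
    rows: list[int] = []
    cols: list[int] = []
    for e_idx, edge in enumerate(edges):
        if edge.bins[-1] >= n:
            raise ValidationError(f"hyperedge {edge.bins} exceeds n_bins={n}")
        for v in edge.bins:
            rows.append(v)
            cols.append(e_idx)
    H = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, m), dtype=np.float64
    )
    if weight_by_frequency and m > 0:
        freqs = np.array([e.frequency for e in edges], dtype=np.float64)
        w = freqs / freqs.mean()
    else:
        w = np.ones(m)
    W = sp.diags(w, shape=(m, m))
    U = sp.diags(np.ones(n), shape=(n, n))
    Dv = sp.diags(np.asarray(H @ w).ravel() if m > 0 else np.zeros(n), shape=(n, n))
    De = sp.diags(np.asarray(H.sum(axis=0)).ravel(), shape=(m, m))
    return Hypergraph(H=H, W=W, U=U, Dv=Dv, De=De)


def propagation_matrix(graph: Hypergraph) -> sp.csr_matrix:
    """Symmetric-normalized propagation operator Dv^-1/2 H W De^-1 H^T Dv^-1/2.

    Zero-degree entries use the pseudo-inverse convention: isolated vertices
    receive (and emit) nothing.
    """
    dv = graph.Dv.diagonal()
    de = graph.De.diagonal()
    with np.errstate(divide="ignore"):
        dv_isqrt = np.where(dv > 0, 1.0 / np.sqrt(np.where(dv > 0, dv, 1.0)), 0.0)
        de_inv = np.where(de > 0, 1.0 / np.where(de > 0, de, 1.0), 0.0)
    left = sp.diags(dv_isqrt) @ graph.H @ graph.W @ sp.diags(de_inv)
    return (left @ graph.H.T @ sp.diags(dv_isqrt)).tocsr()


def contacts_from_reads(
    reads: Iterable[MultiwayRead], bins: GenomeBins
) -> ContactMatrix:
    """Decompose multi-way reads into a symmetric pairwise contact matrix."""
    counts: Counter = Counter()
    for read in reads:
        tup = bin_read(read, bins)
        for i, j in combinations(tup, 2):
            counts[(i, j)] += 1
    n = bins.n_bins
    if counts:
        ij = np.array(list(counts.keys()), dtype=int)
        vals = np.array(list(counts.values()), dtype=np.float64)
        mat = sp.coo_matrix(
            (np.concatenate([vals, vals]), (np.concatenate([ij[:, 0], ij[:, 1]]),
                                            np.concatenate([ij[:, 1], ij[:, 0]]))),
            shape=(n, n),
        ).tocsr()
    else:
        mat = sp.csr_matrix((n, n))
    return ContactMatrix(mat, bins)


# -- serialization -------------------------------------------------------------


def write_hyperedges(edges: HyperedgeSet, path: str | Path) -> None:
    """Hyperedge TSV: ``bins(comma-joined)<TAB>order<TAB>frequency``."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{','.join(map(str, e.bins))}\t{e.order}\t{e.frequency}\n")


def read_hyperedges(path: str | Path, n_bins: int) -> HyperedgeSet:
    out: list[Hyperedge] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            bins_txt, order_txt, freq_txt = line.split("\t")
            bins_tuple = tuple(int(b) for b in bins_txt.split(","))
            if len(bins_tuple) != int(order_txt):
                raise ValidationError(f"order mismatch on line {line.strip()!r}")
            out.append(Hyperedge(bins_tuple, int(freq_txt)))
    return HyperedgeSet(tuple(out), n_bins)


def parse_thresholds(text: str) -> dict[int, int]:
    """Parse CLI threshold syntax ``3:12,4:4,5:3,6:3``."""
    out: dict[int, int] = {}
    for part in text.split(","):
        order_txt, thr_txt = part.split(":")
        out[int(order_txt)] = int(thr_txt)
    return out
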