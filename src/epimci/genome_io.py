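"""Genomic coordinate system and on-disk formats.

All coordinates are 0-based, half-open. The genome is partitioned into
fixed-width, non-overlapping bins; a ``GenomeBins`` object maps (chrom,
position) to a single global bin index shared by every other module.

Formats handled here:

* UCSC ``chrom.sizes`` (two whitespace-separated columns: name, length);
* cluster files (one multi-way read per line: ``read_id chrom:start-end ...``);
* symmetric contact matrices as tab-separated COO text (``bin_i bin_j value``,
  upper triangle on write, either triangle accepted on read);
* an optional cooler adapter behind the same :class:`ContactMatrix` contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 1_000_000

_FRAGMENT_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True)
class GenomeBins:
    """Ordered global index over fixed-width genomic bins across chromosomes."""

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]
    bin_size: int = DEFAULT_BIN_SIZE
    offsets: tuple[int, ...] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValidationError("duplicate chromosome names")
        for name, size in zip(self.chrom_names, self.chrom_sizes):
            if size <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length {size}")
        counts = [-(-size // self.bin_size) for size in self.chrom_sizes]
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(int)
        object.__setattr__(self, "offsets", tuple(int(o) for o in offsets))
        object.__setattr__(self, "n_bins", int(sum(counts)))

    @property
    def chrom_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.chrom_names)}

    def bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(-(-size // self.bin_size) for size in self.chrom_sizes)

    def global_bin(self, chrom: str, position: int) -> int:
        """Global bin index of base ``position`` on ``chrom``."""
        try:
            c = self.chrom_index[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None
        if not 0 <= position < self.chrom_sizes[c]:
            raise ValidationError(
                f"position {position} outside chromosome {chrom} (length {self.chrom_sizes[c]})"
            )
        return self.offsets[c] + position // self.bin_size

    def bin_interval(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) genomic interval of a global bin index."""
        if not 0 <= index < self.n_bins:
            raise ValidationError(f"bin index {index} out of range [0, {self.n_bins})")
        c = int(np.searchsorted(self.offsets, index, side="right")) - 1
        local = index - self.offsets[c]
        start = local * self.bin_size
        end = min(start + self.bin_size, self.chrom_sizes[c])
        return self.chrom_names[c], start, end

    def chrom_of_bin(self, index: int) -> int:
        """Chromosome index containing a global bin index."""
        if not 0 <= index < self.n_bins:
            raise ValidationError(f"bin index {index} out of range [0, {self.n_bins})")
        return int(np.searchsorted(self.offsets, index, side="right")) - 1


@dataclass(frozen=True)
class MultiwayRead:
    """One sequencing read: an identifier plus its list of aligned fragments."""

    read_id: str
    fragments: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        for chrom, start, end in self.fragments:
            if start >= end:
                raise ValidationError(
                    f"read {self.read_id}: fragment {chrom}:{start}-{end} has start >= end"
                )


@dataclass
class ContactMatrix:
    """Symmetric non-negative pairwise contact matrix over genome bins."""

    values: sp.csr_matrix
    bins: GenomeBins

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        n = self.bins.n_bins
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match n_bins={n}"
            )

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        return self.bins == other.bins and (self.values != other.values).nnz == 0


def read_chrom_sizes(path: str | Path, bin_size: int = DEFAULT_BIN_SIZE) -> GenomeBins:
    """Read a UCSC ``chrom.sizes`` file into a :class:`GenomeBins`."""
    names: list[str] = []
    sizes: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(tokens)}")
            name, raw_size = tokens
            try:
                size = int(raw_size)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: length {raw_size!r} is not an integer")
            if size <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive length for {name}")
            if name in names:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            names.append(name)
            sizes.append(size)
    return GenomeBins(tuple(names), tuple(sizes), bin_size)


def write_chrom_sizes(bins: GenomeBins, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in zip(bins.chrom_names, bins.chrom_sizes):
            fh.write(f"{name}\t{size}\n")


def _parse_fragment(token: str, lineno: int, path) -> tuple[str, int, int]:
    m = _FRAGMENT_RE.match(token)
    if m is None:
        raise ParseError(f"{path}:{lineno}: fragment {token!r} does not match chrom:start-end")
    return m["chrom"], int(m["start"]), int(m["end"])


def read_cluster_file(path: str | Path) -> Iterator[MultiwayRead]:
    """Stream multi-way reads from a cluster file.

    Dialect: one read per line; first whitespace-separated token is the read
    id, each remaining token is a fragment ``chrom:start-end``. Empty lines
    are skipped (and logged).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                logger.debug("%s:%d: skipping empty line", path, lineno)
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: read has no fragments")
            fragments = tuple(_parse_fragment(t, lineno, path) for t in tokens[1:])
            yield MultiwayRead(tokens[0], fragments)


def write_cluster_file(reads: Iterable[MultiwayRead], path: str | Path | IO[str]) -> None:
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        for read in reads:
            frags = "\t".join(f"{c}:{s}-{e}" for c, s, e in read.fragments)
            fh.write(f"{read.read_id}\t{frags}\n")
    finally:
        if own:
            fh.close()


def read_contact_coo(path: str | Path, bins: GenomeBins) -> ContactMatrix:
    """Read a tab/whitespace-separated ``bin_i bin_j value`` contact file.

    Values are assigned to both (i, j) and (j, i); duplicate entries sum.
    """
    n = bins.n_bins
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(tokens)}")
            try:
                i, j, v = int(tokens[0]), int(tokens[1]), float(tokens[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: could not parse {line.strip()!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(
                    f"{path}:{lineno}: bin index out of range [0, {n}): {i}, {j}"
                )
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative contact value {v}")
            rows.append(i)
            cols.append(j)
            vals.append(v)
            if i != j:
                rows.append(j)
                cols.append(i)
                vals.append(v)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ContactMatrix(mat, bins)


def write_contact_coo(matrix: ContactMatrix, path: str | Path) -> None:
    """Write the nonzero upper triangle (i <= j) as tab-separated COO text."""
    coo = sp.triu(matrix.values).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for k in order:
            v = coo.data[k]
            text = f"{v:.12g}"
            fh.write(f"{coo.row[k]}\t{coo.col[k]}\t{text}\n")


def read_contact_cooler(path: str | Path, bins: GenomeBins) -> ContactMatrix:
    """Optional adapter: load a ``.cool`` file into the same contract.

    Requires the optional ``cooler`` dependency; the COO text dialect is the
    bit-exact reference format.
    """
    try:
        import cooler
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading .cool files requires the optional 'cooler' package "
            "(pip install epimci[cool]); use COO text otherwise"
        ) from exc
    clr = cooler.Cooler(str(path))
    mat = sp.csr_matrix(clr.matrix(balance=False, sparse=True)[:, :])
    mat = sp.triu(mat)
    mat = mat + sp.triu(mat, k=1).T
    return ContactMatrix(mat.tocsr(), bins)
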