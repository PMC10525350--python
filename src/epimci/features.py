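"""Per-bin epigenomic peak counts and stacked-autoencoder encoding.

Peaks from BED/narrowPeak tracks are midpoint-assigned to genome bins to
form a bins x tracks count table. A two-stage stacked autoencoder (greedy
layer-wise reconstruction training, rectifier encoders) compresses the
z-scored counts to a fixed-width vertex embedding (default widths
[128, 64]); the frozen encoder stack is the feature extractor for the
hyperedge model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Tensor, relu
from .genome_io import GenomeBins, ValidationError
from .optim import Adam

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = (128, 64)
EMBED_DIM = 64


@dataclass
class FeatureTable:
    """Non-negative peak counts, bins x tracks."""

    values: np.ndarray
    track_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.track_names):
            raise ValidationError("feature table shape does not match track names")
        if (self.values < 0).any():
            raise ValidationError("peak counts must be non-negative")


@dataclass
class SAEParams:
    """Frozen stacked-autoencoder parameters plus input standardization."""

    encoder_weights: list[np.ndarray]   # layer l: (in_l, out_l)
    encoder_biases: list[np.ndarray]
    decoder_weights: list[np.ndarray]   # layer l: (out_l, in_l)
    decoder_biases: list[np.ndarray]
    feature_means: np.ndarray
    feature_stds: np.ndarray

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(w.shape[1] for w in self.encoder_weights)

    @property
    def input_dim(self) -> int:
        return self.encoder_weights[0].shape[0]


def count_peaks(bed_path: str | Path, bins: GenomeBins) -> np.ndarray:
    """Count peaks per bin; each peak goes to the bin holding its midpoint.

    Intervals on chromosomes absent from ``bins`` are skipped with a warning.
    The returned vector sums to the number of valid peaks.
    """
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    known = bins.chrom_index
    skipped = 0
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in known:
                skipped += 1
                continue
            midpoint = (start + end) // 2
            counts[bins.global_bin(chrom, midpoint)] += 1
    if skipped:
        logger.warning("%s: skipped %d peaks on unknown chromosomes", bed_path, skipped)
    return counts


def build_feature_table(bed_paths: Sequence[str | Path], bins: GenomeBins) -> FeatureTable:
    names = [Path(p).stem for p in bed_paths]
    values = np.column_stack([count_peaks(p, bins) for p in bed_paths])
    return FeatureTable(values, names)


def standardize(values: np.ndarray, means: np.ndarray, stds: np.ndarray) -> np.ndarray:
    safe = np.where(stds > 0, stds, 1.0)
    return (values - means) / safe


def _train_single_ae(
    x: np.ndarray,
    hidden: int,
    epochs: int,
    lr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Train one autoencoder (rectifier encoder, linear decoder) on ``x``.

    Minimizes the mean squared reconstruction error (1/N) sum_i ||x_i - z_i||^2
    by full-batch Adam; returns encoder/decoder parameters and the loss curve.
    """
    n, d = x.shape
    scale_in = np.sqrt(6.0 / (d + hidden))
    w_enc = Tensor(rng.uniform(-scale_in, scale_in, size=(d, hidden)), requires_grad=True)
    b_enc = Tensor(np.zeros(hidden), requires_grad=True)
    w_dec = Tensor(rng.uniform(-scale_in, scale_in, size=(hidden, d)), requires_grad=True)
    b_dec = Tensor(np.zeros(d), requires_grad=True)
    params = [w_enc, b_enc, w_dec, b_dec]
    opt = Adam(params, lr=lr)
    xt = Tensor(x)
    curve: list[float] = []
    for _ in range(epochs):
        hidden_act = relu(xt @ w_enc + b_enc)
        recon = hidden_act @ w_dec + b_dec
        loss = ((xt - recon) ** 2).sum(axis=1).mean()
        if not np.isfinite(loss.item()):
            raise FloatingPointError("non-finite SAE reconstruction loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
        curve.append(loss.item())
    return w_enc.data, b_enc.data, w_dec.data, b_dec.data, curve


def reconstruction_loss(x: np.ndarray, z: np.ndarray) -> float:
    """Mean over rows of the squared reconstruction error ||x_i - z_i||^2."""
    return float(np.mean(np.sum((x - z) ** 2, axis=1)))


def train_sae(
    features: FeatureTable,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    epochs: int = 200,
    lr: float = 1e-3,
    seed: int = 0,
) -> SAEParams:
    """Greedy layer-wise stacked-autoencoder training.

    Tracks are z-scored, the first autoencoder reconstructs the standardized
    counts, and each subsequent autoencoder reconstructs the previous hidden
    layer. The final hidden layer is the vertex embedding.
    """
    if features.values.shape[1] < 1:
        raise ValidationError("feature table must have at least one track")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    means = features.values.mean(axis=0)
    stds = features.values.std(axis=0)
    x = standardize(features.values.astype(np.float64), means, stds)
    enc_w, enc_b, dec_w, dec_b = [], [], [], []
    for hidden in widths:
        w1, b1, w2, b2, curve = _train_single_ae(x, hidden, epochs, lr, rng)
        if epochs >= 2 and curve[-1] > curve[0]:
            logger.warning("SAE layer loss increased: %.4g -> %.4g", curve[0], curve[-1])
        enc_w.append(w1)
        enc_b.append(b1)
        dec_w.append(w2)
        dec_b.append(b2)
        x = np.maximum(x @ w1 + b1, 0.0)
    return SAEParams(enc_w, enc_b, dec_w, dec_b, means, stds)


def encode(params: SAEParams, features: FeatureTable) -> np.ndarray:
    """Apply the frozen encoder stack: returns the N x widths[-1] embeddings."""
    if features.values.shape[1] != params.input_dim:
        raise ValidationError(
            f"feature width {features.values.shape[1]} does not match "
            f"trained width {params.input_dim}"
        )
    x = standardize(features.values.astype(np.float64), params.feature_means, params.feature_stds)
    for w, b in zip(params.encoder_weights, params.encoder_biases):
        x = np.maximum(x @ w + b, 0.0)
    return x


# -- serialization -------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\t" + "\t".join(table.track_names) + "\n")
        for i, row in enumerate(table.values):
            fh.write(f"{i}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().split()
        names = header[1:]
        rows = [[int(v) for v in line.split()[1:]] for line in fh if line.strip()]
    return FeatureTable(np.array(rows, dtype=np.int64), names)


def write_embeddings(embeddings: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(embeddings):
            fh.write(f"{i}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_embeddings(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append([float(v) for v in line.split()[1:]])
    return np.array(rows, dtype=np.float64)
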