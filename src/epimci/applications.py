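"""Case studies: likelihood denoising of contact maps and compartment PCA.

The trained scorer is applied to every unordered pair of genome bins to
produce a symmetric likelihood matrix; the element-wise product with an
observed pairwise contact matrix downweights contacts the model considers
implausible. Separately, fused per-vertex embeddings are extracted and
projected with PCA; when compartment annotations are supplied, the first
principal component is scored as a one-dimensional A/B separator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .autograd import Tensor, concat, relu
from .genome_io import ContactMatrix, GenomeBins, ValidationError
from .hypergraph import Hypergraph
from .model import ModelParams, hconv, score_tuples


@dataclass
class LikelihoodMatrix:
    """Symmetric matrix of pairwise hyperedge probabilities, diagonal fixed to 1."""

    values: np.ndarray
    bins: GenomeBins

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.bins.n_bins
        if self.values.shape != (n, n):
            raise ValidationError("likelihood matrix shape does not match bins")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValidationError("likelihood entries must lie in [0, 1]")


def pairwise_likelihood(
    params: ModelParams,
    bins: GenomeBins,
    embeddings: np.ndarray,
    graph: Hypergraph | None,
    pair_mode: str = "direct",
    window: int = 10,
    batch_size: int = 4096,
) -> LikelihoodMatrix:
    """Score all C(N, 2) bin pairs with the trained model.

    ``direct`` feeds each pair as a masked order-2 tuple (attention over the
    single neighbor is well defined); ``triplet-max`` instead scores every
    completion (i, j, k) with k drawn from a +/- ``window`` neighbourhood of
    either endpoint and takes the maximum — for models that should only ever
    see orders >= 3. The diagonal is fixed to 1 by convention.
    """
    n = bins.n_bins
    pairs = list(combinations(range(n), 2))
    if pair_mode == "direct":
        scores = score_tuples(params, pairs, embeddings, graph, batch_size)
    elif pair_mode == "triplet-max":
        per_chrom = bins.bins_per_chrom()
        triples: list[tuple[int, ...]] = []
        owner: list[int] = []
        for pi, (i, j) in enumerate(pairs):
            candidates: set[int] = set()
            for anchor in (i, j):
                c = bins.chrom_of_bin(anchor)
                lo = bins.offsets[c]
                hi = lo + per_chrom[c]
                candidates.update(range(max(lo, anchor - window), min(hi, anchor + window + 1)))
            candidates -= {i, j}
            for k in candidates:
                triples.append(tuple(sorted((i, j, k))))
                owner.append(pi)
        completion_scores = score_tuples(params, triples, embeddings, graph, batch_size)
        scores = np.zeros(len(pairs))
        np.maximum.at(scores, np.asarray(owner), completion_scores)
    else:
        raise ValidationError(f"unknown pair_mode {pair_mode!r}")
    values = np.ones((n, n))
    idx = np.array(pairs)
    values[idx[:, 0], idx[:, 1]] = scores
    values[idx[:, 1], idx[:, 0]] = scores
    return LikelihoodMatrix(values, bins)


def denoise(likelihood: LikelihoodMatrix, contacts: ContactMatrix) -> ContactMatrix:
    """Element-wise product of likelihood and contacts.

    Never increases any entry (likelihood <= 1); preserves symmetry and
    non-negativity.
    """
    if likelihood.bins.n_bins != contacts.bins.n_bins:
        raise ValidationError("likelihood and contact matrices have different sizes")
    out = contacts.values.multiply(likelihood.values).tocsr()
    return ContactMatrix(out, contacts.bins)


def extract_embeddings(
    params: ModelParams,
    graph: Hypergraph | None,
    embeddings: np.ndarray,
    stage: str = "fused",
) -> np.ndarray:
    """Per-vertex representations from the trained model.

    The discrete channel passes each vertex's own feature through the MLP
    path; the structural channel runs the hypergraph convolution over the
    full positive hypergraph. ``stage`` selects the concatenated pre-fusion
    representation (``"pre"``) or the dense fusion layer output
    (``"fused"``, default).
    """
    cfg = params.config
    n = embeddings.shape[0]
    parts: list[Tensor] = []
    if cfg.variant != "noSHE":
        x = Tensor(embeddings)
        h1 = relu(x @ params["mlp_w1"] + params["mlp_b1"])
        h2 = relu(h1 @ params["mlp_w2"] + params["mlp_b2"])
        e_ind = h2 @ params["mlp_w3"] + params["mlp_b3"]
        if cfg.pool == "concat":
            parts.append(concat([e_ind, e_ind], axis=-1))
        else:
            parts.append(e_ind)
    if cfg.variant != "noCHE":
        if graph is None:
            raise ValidationError("coupling channel needs a hypergraph")
        parts.append(hconv(embeddings, graph, params))
    pre = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
    if stage == "pre":
        return pre.data.copy()
    if stage != "fused":
        raise ValidationError(f"unknown stage {stage!r}")
    fused = relu(pre @ params["fusion_w"] + params["fusion_b"])
    return fused.data.copy()


@dataclass
class SeparationReport:
    """How well PC1 separates compartment annotations."""

    pc1_auc: float | None
    explained_variance_ratio: np.ndarray
    per_chrom_dispersion: dict[str, float] | None = None


def pca_compartments(
    embeddings: np.ndarray,
    labels: Sequence[str] | None = None,
    n_components: int = 2,
    bins: GenomeBins | None = None,
    standardize: bool = False,
) -> tuple[np.ndarray, SeparationReport | None]:
    """Mean-centered PCA projection plus an optional separation report.

    With labels, reports the direction-independent AUC of PC1 as a
    one-dimensional separator of the two majority classes (A-like vs B-like:
    labels are grouped by their leading letter, so sub-compartment labels
    A1/A2/B1/B2/B3 collapse onto A vs B), and — when ``bins`` is given — the
    per-chromosome dispersion ratio in the projected plane (values near 1
    mean no chromosome clustering). ``standardize`` additionally scales each
    embedding dimension to unit variance before the decomposition, which
    stops a few high-variance structural dimensions from dominating PC1.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] < n_components:
        raise ValidationError("need at least n_components rows")
    if np.allclose(embeddings.std(axis=0), 0.0):
        raise ValidationError("constant embeddings: PCA undefined")
    if standardize:
        sd = embeddings.std(axis=0)
        embeddings = (embeddings - embeddings.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components)
    projection = pca.fit_transform(embeddings)
    if labels is None:
        return projection, None
    groups = np.array([str(lab)[0] for lab in labels])
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValidationError(f"expected two compartment groups, got {list(uniq)}")
    y = (groups == uniq[0]).astype(int)
    auc = float(roc_auc_score(y, projection[:, 0]))
    auc = max(auc, 1.0 - auc)  # PCA sign is arbitrary
    per_chrom = None
    if bins is not None:
        per_chrom = {}
        total_var = projection.var(axis=0).sum()
        for c, name in enumerate(bins.chrom_names):
            sel = slice(bins.offsets[c], bins.offsets[c] + bins.bins_per_chrom()[c])
            per_chrom[name] = float(projection[sel].var(axis=0).sum() / total_var)
    report = SeparationReport(auc, pca.explained_variance_ratio_, per_chrom)
    return projection, report


def matrix_correlation(
    a: ContactMatrix, b: ContactMatrix, transform: str = "log1p"
) -> float:
    """Pearson correlation of off-diagonal upper-triangle entries.

    ``transform="log1p"`` (default) compresses the heavy-tailed contact
    counts before correlating, the usual practice when comparing contact
    maps; ``"raw"`` correlates the untransformed entries.
    """
    da, db = a.dense(), b.dense()
    iu = np.triu_indices_from(da, k=1)
    x, y = da[iu], db[iu]
    if transform == "log1p":
        x, y = np.log1p(x), np.log1p(y)
    elif transform != "raw":
        raise ValidationError(f"unknown transform {transform!r}")
    return float(np.corrcoef(x, y)[0, 1])
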