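import numpy as np
import pytest

from epimci.genome_io import GenomeBins


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_bins():
    """Two chromosomes of 5 and 3 Mb at 1 Mb resolution (8 bins)."""
    return GenomeBins(("chr1", "chr2"), (5_000_000, 3_000_000), 1_000_000)


@pytest.fixture
def toy_bins():
    """One chromosome, 10 bins."""
    return GenomeBins(("chr1",), (10_000_000,), 1_000_000)


def assert_gradients_match(loss_value, params, rng, n_coords=3, rel=1e-4, abs_tol=1e-7):
    """Central-difference check of autodiff gradients on sampled coordinates.

    Rectifier networks are only piecewise smooth: a finite-difference step
    that crosses a kink gives a spurious numeric estimate. Each coordinate
    is therefore also evaluated with a 10x smaller step and accepted if
    either estimate matches the analytic gradient.
    """
    import pytest

    loss = loss_value()
    for t in params.all_tensors():
        t.zero_grad()
    loss.backward()
    for name in sorted(params.tensors):
        tensor = params.tensors[name]
        grad = tensor.grad
        assert grad is not None, name
        flat = tensor.data.ravel()
        for i in rng.choice(flat.size, size=min(n_coords, flat.size), replace=False):
            estimates = []
            for eps in (1e-6, 1e-7):
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss_value().item()
                flat[i] = orig - eps
                lo = loss_value().item()
                flat[i] = orig
                estimates.append((hi - lo) / (2 * eps))
            analytic = grad.ravel()[i]
            assert any(
                analytic == pytest.approx(num, rel=rel, abs=abs_tol) for num in estimates
            ), f"{name}[{i}]: analytic {analytic}, numeric {estimates}"


def random_hypergraph(rng, n_max=10, m_max=6, n=None):
    """A random small hyperedge set (orders 3..6) for oracle comparisons."""
    from epimci.hypergraph import Hyperedge, HyperedgeSet

    if n is None:
        n = int(rng.integers(6, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    edges = set()
    while len(edges) < m:
        order = int(rng.integers(3, min(6, n) + 1))
        edges.add(tuple(sorted(rng.choice(n, size=order, replace=False).tolist())))
    hyperedges = tuple(
        Hyperedge(bins, int(rng.integers(1, 20))) for bins in sorted(edges)
    )
    return HyperedgeSet(hyperedges, n)
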