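import numpy as np
import pandas as pd
import pytest

from emixed import dnam, rna, simulate
from emixed.types import BulkMatrix, CellFractions, MethylSignature, ProfileMatrix


@pytest.fixture
def toy_profile() -> ProfileMatrix:
    """Two well-separated cell types over two genes."""
    return rna.normalize_profile(
        pd.DataFrame({"alpha": [0.9, 0.1], "beta": [0.1, 0.9]}, index=["g1", "g2"])
    )


@pytest.fixture
def toy_signature() -> MethylSignature:
    """Mirror-marker signature: locus 1 methylated in type alpha, locus 2 in beta."""
    return MethylSignature(
        ["cg1", "cg2"], ["alpha", "beta"], np.array([[0.9, 0.1], [0.1, 0.9]])
    )


@pytest.fixture
def small_dataset():
    """Matched multi-omics dataset small enough for fast end-to-end tests."""
    cfg = simulate.SimulationConfig(
        n_samples=8,
        n_genes=120,
        n_loci=150,
        depth=50_000,
        coverage=500,
        cell_sizes=(0.6, 1.0, 1.4),
        seed=11,
    )
    return simulate.simulate_dataset(cfg)


def grid_search_rna(x, A, step=1e-4):
    """Brute-force maximizer of the RNA log-likelihood over theta1 (K=2).

    Independent of the EM path: evaluates sum_i x_i log(A @ theta) on a dense
    grid of the one free parameter.
    """
    t1 = np.arange(0.0, 1.0 + step / 2, step)
    thetas = np.column_stack([t1, 1.0 - t1])
    mix = thetas @ A.values.T  # grid x I
    nz = x > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (np.log(mix[:, nz]) * x[nz]).sum(axis=1)
    ll[~np.isfinite(ll)] = -np.inf
    return thetas[np.argmax(ll)]


def grid_search_dnam(meth, cov, pi, step=1e-4):
    """Brute-force maximizer of the DNAm log-likelihood over theta1 (K=2)."""
    t1 = np.arange(0.0, 1.0 + step / 2, step)
    thetas = np.column_stack([t1, 1.0 - t1])
    p1 = thetas @ pi.values.T  # grid x G
    p0 = thetas @ (1.0 - pi.values).T
    if cov is None:
        w1, w0 = meth, 1.0 - meth
    else:
        w1, w0 = meth, cov - meth
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (np.log(p1) * w1).sum(axis=1) + (np.log(p0) * w0).sum(axis=1)
    ll[~np.isfinite(ll)] = -np.inf
    return thetas[np.argmax(ll)]


def random_rna_instance(rng, I=30, K=3):
    """A random bulk column + profile pair for property tests."""
    raw = rng.gamma(1.0, 1.0, size=(I, K)) + 1e-3
    A = ProfileMatrix(
        [f"g{i}" for i in range(I)],
        [f"t{k}" for k in range(K)],
        raw / raw.sum(axis=0),
    )
    theta = rng.dirichlet(np.ones(K))
    x = rng.multinomial(2000, A.values @ theta).astype(float)
    return x, A, theta


def random_dnam_instance(rng, G=40, K=3, D=50):
    """A random methylation-count instance for property tests."""
    pi = MethylSignature(
        [f"cg{g}" for g in range(G)],
        [f"t{k}" for k in range(K)],
        np.clip(rng.beta(0.5, 0.5, size=(G, K)), 1e-6, 1 - 1e-6),
    )
    theta = rng.dirichlet(np.ones(K))
    cov = np.full(G, float(D))
    meth = rng.binomial(D, pi.values @ theta).astype(float)
    return meth, cov, pi, theta
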