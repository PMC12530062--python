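"""Matched multi-omics pseudobulk simulation with known ground-truth fractions.

Both simulators draw from the same generative models the estimators assume.
RNA: each read picks a cell type (multinomial in the transcript-level
fractions) and then a gene from that type's profile column, so gene counts
are Multinomial(depth, A @ theta_tilde).  DNAm: each molecule covering a
locus picks a cell type and is methylated with that type's signature
probability, so methylated counts are Binomial(coverage, pi[g] @ theta) — the
Binomial shortcut is the exact marginal of the molecule-level process, which
is kept as a slow reference implementation for cross-checks.

Cell sizes enter the RNA path only: transcript-level fractions are
``theta * S / sum(theta * S)``, the inverse of the cell-size adjustment, so
end-to-end recovery exercises that conversion.  DNA copy number per cell is
treated as constant, so DNAm uses ``theta`` directly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .types import (
    BulkMatrix,
    CellFractions,
    CellSizes,
    MethylSignature,
    ProfileMatrix,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "simulate_fractions",
    "simulate_reference_rna",
    "simulate_bulk_rna",
    "simulate_reference_dnam",
    "simulate_bulk_dnam",
    "simulate_bulk_dnam_molecular",
    "perturb_profile",
    "perturb_signature",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic multi-omics dataset.

    n_cell_types: K, number of cell types.
    n_genes / n_loci: RNA features I and CpG loci G.
    n_samples: N bulk samples.
    alpha: symmetric Dirichlet concentration for the true fractions; 1 is
        flat over the simplex.
    marker_strength: fold elevation of each type's marker-gene block in the
        RNA reference; 1 means no signal.
    pi_a, pi_b: Beta parameters shaping the DNAm signature; marker loci of a
        type draw Beta(pi_a, pi_b) in that type (high methylation for the
        defaults) and Beta(pi_b, pi_a) elsewhere, so a = b gives a symmetric
        signature distribution.
    depth: RNA sequencing depth R_n per sample.
    coverage: DNAm coverage D per locus; a scalar gives constant coverage
        (the array-mode assumption), 'poisson' draws per-locus Poisson
        coverage around coverage_mean.
    cell_sizes: average transcripts per cell per type; None means all equal.
    seed: base seed; every simulator is deterministic given it.
    """

    n_cell_types: int = 3
    n_genes: int = 200
    n_loci: int = 500
    n_samples: int = 50
    alpha: float = 1.0
    marker_strength: float = 20.0
    pi_a: float = 8.0
    pi_b: float = 2.0
    depth: int = 100_000
    coverage: int = 1000
    coverage_poisson: bool = False
    cell_sizes: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_genes, self.n_loci, self.n_samples) < 1:
            raise ValidationError("all simulation sizes must be positive")
        if self.n_genes < self.n_cell_types or self.n_loci < self.n_cell_types:
            raise ValidationError("need at least one feature per cell type")
        if self.alpha <= 0:
            raise ValidationError("Dirichlet concentration must be positive")
        if self.depth < 1 or self.coverage < 1:
            raise ValidationError("depth and coverage must be positive")
        if self.marker_strength < 1:
            raise ValidationError("marker strength must be >= 1")
        if self.cell_sizes is not None:
            s = np.asarray(self.cell_sizes, dtype=float)
            if s.shape != (self.n_cell_types,) or np.any(s <= 0):
                raise ValidationError(
                    "cell_sizes must be one positive value per cell type"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def cell_type_labels(self) -> list:
        return [f"type{k + 1}" for k in range(self.n_cell_types)]


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_fractions(cfg: SimulationConfig) -> CellFractions:
    """Ground-truth fractions: N rows from a symmetric Dirichlet(alpha)."""
    rng = _rng(cfg.seed, 0)
    theta = rng.dirichlet(np.full(cfg.n_cell_types, cfg.alpha), size=cfg.n_samples)
    samples = [f"sample{n + 1}" for n in range(cfg.n_samples)]
    return CellFractions(samples, cfg.cell_type_labels, theta)


def simulate_reference_rna(cfg: SimulationConfig) -> tuple[ProfileMatrix, np.ndarray]:
    """Block-marker RNA reference and per-type library sizes.

    Each cell type receives an equal block of marker genes whose raw mass is
    ``marker_strength`` times a shared per-gene baseline; columns are then
    normalized to sum 1.  Returns the profile and the raw library sizes used
    to derive cell sizes (library size is proportional to transcripts per
    cell).
    """
    rng = _rng(cfg.seed, 1)
    I, K = cfg.n_genes, cfg.n_cell_types
    baseline = rng.uniform(0.5, 1.5, size=I)
    raw = np.tile(baseline[:, None], (1, K))
    block = I // K
    for k in range(K):
        lo = k * block
        hi = I if k == K - 1 else (k + 1) * block
        raw[lo:hi, k] *= cfg.marker_strength
    A = raw / raw.sum(axis=0)
    genes = [f"gene{i + 1}" for i in range(I)]
    if cfg.cell_sizes is not None:
        lib_sizes = 10_000.0 * np.asarray(cfg.cell_sizes, dtype=float)
    else:
        lib_sizes = np.full(K, 10_000.0)
    return ProfileMatrix(genes, cfg.cell_type_labels, A), lib_sizes


def _transcript_fractions(theta: np.ndarray, S: CellSizes | None) -> np.ndarray:
    if S is None:
        return theta
    w = theta * S.values
    return w / w.sum(axis=-1, keepdims=True)


def simulate_bulk_rna(
    theta: CellFractions,
    A: ProfileMatrix,
    S: CellSizes | None = None,
    depth: int = 100_000,
    seed: int = 0,
) -> BulkMatrix:
    """Draw bulk RNA counts: Multinomial(depth, A @ transcript fractions).

    ``theta`` holds *cell* fractions; each sample's transcript-level mixture
    weight is ``theta * S`` renormalized, so that fitting followed by the
    cell-size adjustment recovers ``theta``.
    """
    if list(theta.cell_types) != list(A.cell_types):
        raise ValidationError("fraction and profile cell-type labels differ")
    rng = np.random.default_rng(seed)
    theta_tilde = _transcript_fractions(theta.values, S)
    probs = theta_tilde @ A.values.T  # N x I
    counts = np.empty((A.n_features, theta.n_samples))
    for n in range(theta.n_samples):
        counts[:, n] = rng.multinomial(depth, probs[n])
    return BulkMatrix(list(A.features), list(theta.samples), counts, "rna_counts")


def simulate_reference_dnam(cfg: SimulationConfig) -> MethylSignature:
    """Block-marker DNAm signature with per-type discriminating loci.

    Marker loci of type ``k`` draw methylation probability Beta(pi_a, pi_b)
    in type ``k`` and Beta(pi_b, pi_a) in the other types; with the defaults
    (8, 2) markers are strongly methylated in their own type and weakly
    elsewhere, giving loci near 0 or 1 as in real sorted-cell signatures.
    """
    rng = _rng(cfg.seed, 2)
    G, K = cfg.n_loci, cfg.n_cell_types
    pi = rng.beta(cfg.pi_b, cfg.pi_a, size=(G, K))
    block = G // K
    for k in range(K):
        lo = k * block
        hi = G if k == K - 1 else (k + 1) * block
        pi[lo:hi, k] = rng.beta(cfg.pi_a, cfg.pi_b, size=hi - lo)
    loci = [f"cg{g + 1:06d}" for g in range(G)]
    return MethylSignature(loci, cfg.cell_type_labels, pi)


def _coverage_matrix(
    cfg_or_cov, G: int, N: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(cfg_or_cov, SimulationConfig):
        if cfg_or_cov.coverage_poisson:
            cov = rng.poisson(cfg_or_cov.coverage, size=(G, N)).astype(float)
        else:
            cov = np.full((G, N), float(cfg_or_cov.coverage))
    else:
        cov = np.broadcast_to(np.asarray(cfg_or_cov, dtype=float), (G, N)).copy()
    return cov


def simulate_bulk_dnam(
    theta: CellFractions,
    pi: MethylSignature,
    coverage=1000,
    seed: int = 0,
) -> tuple[BulkMatrix, BulkMatrix]:
    """Draw bulk DNAm counts and the derived beta matrix.

    Methylated counts are Binomial(D[g, n], pi[g] @ theta_n) — the exact
    marginal of drawing each molecule's cell type and then its methylation
    status.  Returns ``(counts, betas)``; betas are methylated / coverage
    where coverage is positive and 0 elsewhere.  ``coverage`` may be a
    scalar, a G x N array, or a SimulationConfig (honouring its Poisson
    option).
    """
    if list(theta.cell_types) != list(pi.cell_types):
        raise ValidationError("fraction and signature cell-type labels differ")
    rng = np.random.default_rng(seed)
    G, N = pi.n_loci, theta.n_samples
    cov = _coverage_matrix(coverage, G, N, rng)
    p = pi.values @ theta.values.T  # G x N
    meth = rng.binomial(cov.astype(int), p).astype(float)
    counts = BulkMatrix(
        list(pi.loci), list(theta.samples), meth, "dnam_counts", coverage=cov
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(cov > 0, meth / np.where(cov > 0, cov, 1.0), 0.0)
    betas = BulkMatrix(list(pi.loci), list(theta.samples), beta, "dnam_beta")
    return counts, betas


def simulate_bulk_dnam_molecular(
    theta_row: np.ndarray,
    pi: MethylSignature,
    coverage: int,
    seed: int = 0,
) -> np.ndarray:
    """Slow molecule-level reference path for one sample.

    Draws each molecule's cell type explicitly and then its Bernoulli
    methylation status; exists only to cross-check that the Binomial shortcut
    in :func:`simulate_bulk_dnam` is the exact marginal.
    """
    rng = np.random.default_rng(seed)
    theta_row = np.asarray(theta_row, dtype=float)
    G, K = pi.values.shape
    meth = np.zeros(G)
    for g in range(G):
        types = rng.choice(K, size=coverage, p=theta_row)
        meth[g] = (rng.random(coverage) < pi.values[g, types]).sum()
    return meth


def perturb_profile(
    A: ProfileMatrix, sd: float, seed: int = 0
) -> ProfileMatrix:
    """Stress-test variant of a profile: multiplicative Gaussian noise.

    Each entry is scaled by ``exp(N(0, sd))`` and columns renormalized,
    emulating a mismatched reference built from a different cohort or
    platform.
    """
    rng = np.random.default_rng(seed)
    vals = A.values * np.exp(rng.normal(0.0, sd, size=A.values.shape))
    vals = np.clip(vals, 0.0, None)
    return ProfileMatrix(list(A.features), list(A.cell_types), vals / vals.sum(axis=0))


def perturb_signature(
    pi: MethylSignature, sd: float, seed: int = 0
) -> MethylSignature:
    """Stress-test variant of a signature: additive Gaussian noise, truncated."""
    rng = np.random.default_rng(seed)
    vals = np.clip(pi.values + rng.normal(0.0, sd, size=pi.values.shape), 0.0, 1.0)
    return MethylSignature(list(pi.loci), list(pi.cell_types), vals)


def simulate_dataset(cfg: SimulationConfig) -> dict:
    """Generate one matched multi-omics dataset under ``cfg``.

    Returns a dict with the true fractions, RNA reference + library sizes,
    DNAm signature, bulk RNA counts, bulk DNAm counts + betas, the cell-size
    vector, and the resolved config (seed included) for provenance.
    """
    theta = simulate_fractions(cfg)
    A, lib_sizes = simulate_reference_rna(cfg)
    pi = simulate_reference_dnam(cfg)
    S = CellSizes(cfg.cell_type_labels, lib_sizes / lib_sizes.mean())
    rna_seed = int(_rng(cfg.seed, 3).integers(2**31))
    dnam_seed = int(_rng(cfg.seed, 4).integers(2**31))
    bulk_rna = simulate_bulk_rna(theta, A, S, depth=cfg.depth, seed=rna_seed)
    dnam_counts, dnam_beta = simulate_bulk_dnam(theta, pi, cfg, seed=dnam_seed)
    return {
        "config": cfg.to_dict(),
        "fractions": theta,
        "profile": A,
        "library_sizes": lib_sizes,
        "cell_sizes": S,
        "signature": pi,
        "bulk_rna": bulk_rna,
        "bulk_dnam_counts": dnam_counts,
        "bulk_dnam_beta": dnam_beta,
    }
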