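"""EM deconvolution of bulk RNA-seq counts under a multinomial allocation model.

The generative model assigns each sequenced read first to a cell type (a
multinomial draw from the sample's fraction vector ``theta``) and then to a
gene (a multinomial draw from that cell type's expression profile, column
``A[:, k]`` of the reference).  Marginally the gene counts of sample ``n`` are

    X[:, n] ~ Multinomial(R_n, A @ theta_n),

a mixture of multinomials, so ``theta_n`` is estimated by EM with closed-form
steps:

    E-step:  psi[i, k] = X[i] * A[i, k] * theta[k] / sum_k' A[i, k'] * theta[k']
    M-step:  theta[k]  = sum_i psi[i, k] / sum_{i,k'} psi[i, k']

``theta`` here is the fraction of *transcripts* per cell type (RNA fractions).
Cell types differ in transcripts per cell, so converting to fractions of
*cells* divides by the cell-size vector ``S`` and renormalizes
(:func:`adjust_cell_size`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import Config
from .types import (
    BulkMatrix,
    CellFractions,
    CellSizes,
    FitResult,
    ProfileMatrix,
    ValidationError,
)

__all__ = [
    "normalize_profile",
    "rna_e_step",
    "rna_m_step",
    "rna_log_likelihood",
    "fit_rna",
    "adjust_cell_size",
    "adjust_fractions",
    "estimate_cell_sizes",
]

logger = logging.getLogger("emixed")


def normalize_profile(raw_ref: pd.DataFrame) -> ProfileMatrix:
    """Column-normalize a raw cell-type expression matrix into a profile.

    All-zero gene rows are removed (with a logged count) before dividing each
    column by its sum, so each column becomes a probability distribution over
    the retained genes.

    Parameters
    ----------
    raw_ref
        Genes x cell types matrix of non-negative average expression values,
        e.g. mean counts per cell type from a sorted or single-cell reference.
    """
    vals = raw_ref.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValidationError("reference expression must be non-negative")
    keep = vals.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("normalize_profile: dropped %d all-zero gene row(s)", n_dropped)
        vals = vals[keep]
    colsums = vals.sum(axis=0)
    if np.any(colsums <= 0):
        bad = raw_ref.columns[int(np.argmin(colsums))]
        raise ValidationError(f"cell type {bad!r} has zero total expression")
    return ProfileMatrix(
        list(raw_ref.index[keep]), list(raw_ref.columns), vals / colsums
    )


def _mixture(A: np.ndarray, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-gene mixture mass ``(A @ theta)``, validated where reads exist."""
    mix = A @ theta
    bad = (x > 0) & (mix <= 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValidationError(
            f"gene index {i} has observed reads but zero reference mass under "
            "the current fractions; the reference cannot explain the bulk data"
        )
    return mix


def rna_e_step(x: np.ndarray, A: ProfileMatrix, theta: np.ndarray) -> np.ndarray:
    """Expected per-gene read allocations ``psi`` (I x K) for one sample.

    Conserves reads: ``psi.sum(axis=1) == x`` exactly up to float error; genes
    with zero counts get all-zero rows.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    mix = _mixture(A.values, theta, x)
    psi = np.zeros((A.n_features, A.n_cell_types))
    nz = x > 0
    psi[nz] = (x[nz, None] / mix[nz, None]) * A.values[nz] * theta
    return psi


def rna_m_step(psi: np.ndarray) -> np.ndarray:
    """Maximizing fractions: normalized column sums of the allocations."""
    col = np.asarray(psi, dtype=float).sum(axis=0)
    total = col.sum()
    if total <= 0:
        raise ValidationError("no reads allocated; cannot update fractions")
    return col / total


def rna_log_likelihood(x: np.ndarray, A: ProfileMatrix, theta: np.ndarray) -> float:
    """Observed-data log-likelihood up to a theta-free constant.

    ``sum_i X[i] * log(sum_k A[i, k] theta[k])``; used to verify the EM
    monotonicity guarantee and as a convergence diagnostic.
    """
    x = np.asarray(x, dtype=float)
    mix = _mixture(A.values, np.asarray(theta, dtype=float), x)
    nz = x > 0
    return float(x[nz] @ np.log(mix[nz]))


def _fit_one_rna(
    x: np.ndarray, A: ProfileMatrix, cfg: Config
) -> tuple[np.ndarray, int, np.ndarray, bool]:
    K = A.n_cell_types
    theta = np.full(K, 1.0 / K)
    nz = x > 0
    xv, Av = x[nz], A.values[nz]
    total = xv.sum()
    trace = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        mix = Av @ theta
        if np.any(mix <= 0):
            raise ValidationError(
                "a gene with observed reads has zero reference mass under the "
                "current fractions"
            )
        # fused E+M: new theta_k = theta_k * sum_i A_ik x_i / mix_i / R_n
        theta_new = theta * (Av.T @ (xv / mix)) / total
        theta_new /= theta_new.sum()
        trace.append(float(xv @ np.log(Av @ theta_new)))
        delta = np.max(np.abs(theta_new - theta))
        theta = theta_new
        if delta < cfg.tol:
            converged = True
            break
    return theta, it, np.asarray(trace), converged


def fit_rna(
    bulk: BulkMatrix, A: ProfileMatrix, opts: Config | None = None
) -> FitResult:
    """Fit per-sample RNA fractions by EM, each sample independently.

    Features of ``bulk`` and ``A`` must already be aligned (same identifiers
    in the same order); use :func:`emixed.io.align_features` first.
    Initialization is uniform: the log-likelihood is concave in ``theta``, so
    the optimum does not depend on the start.  Non-convergence within
    ``opts.max_iter`` is flagged in the result, not raised.
    """
    opts = opts or Config()
    if bulk.modality != "rna_counts":
        raise ValidationError(f"fit_rna expects rna_counts, got {bulk.modality!r}")
    if list(bulk.features) != list(A.features):
        raise ValidationError(
            "bulk and profile features differ; align with io.align_features first"
        )
    K = A.n_cell_types
    if K > 1 and np.allclose(
        A.values, A.values[:, :1], rtol=0, atol=1e-12
    ):
        logger.warning(
            "all profile columns are identical: the reference carries no "
            "cell-type signal and every fraction vector fits equally well"
        )
    thetas = np.empty((bulk.n_samples, K))
    iters = np.empty(bulk.n_samples, dtype=int)
    traces, conv = [], np.empty(bulk.n_samples, dtype=bool)
    for n in range(bulk.n_samples):
        if K == 1:
            thetas[n], iters[n], conv[n] = 1.0, 1, True
            traces.append(
                np.asarray([rna_log_likelihood(bulk.values[:, n], A, np.ones(1))])
            )
            continue
        thetas[n], iters[n], trace, conv[n] = _fit_one_rna(
            bulk.values[:, n], A, opts
        )
        traces.append(trace)
        if not conv[n]:
            logger.warning(
                "sample %r did not converge in %d iterations",
                bulk.samples[n],
                opts.max_iter,
            )
    fractions = CellFractions(list(bulk.samples), list(A.cell_types), thetas)
    return FitResult(
        fractions=fractions,
        iterations=iters,
        loglik_trace=traces,
        converged=conv,
    )


def adjust_cell_size(theta_rna: np.ndarray, S: CellSizes) -> np.ndarray:
    """Convert RNA (transcript) fractions to cell fractions.

    ``theta_cell[k] = (theta[k] / S[k]) / sum_k' (theta[k'] / S[k'])`` —
    dividing out the average transcripts-per-cell of each type.  Invariant to
    rescaling ``S``; applied once to the converged ``theta`` since it is a
    deterministic bijection that does not feed back into the EM updates.
    """
    theta = np.asarray(theta_rna, dtype=float)
    if theta.ndim == 1:
        w = theta / S.values
        return w / w.sum()
    w = theta / S.values[None, :]
    return w / w.sum(axis=1, keepdims=True)


def adjust_fractions(fr: CellFractions, S: CellSizes) -> CellFractions:
    """Apply :func:`adjust_cell_size` to every sample of a fraction table."""
    if list(fr.cell_types) != list(S.cell_types):
        raise ValidationError("cell-size labels do not match fraction columns")
    return CellFractions(list(fr.samples), list(fr.cell_types), adjust_cell_size(fr.values, S))


def estimate_cell_sizes(ref_library_sizes, cell_types=None) -> CellSizes:
    """Cell sizes from per-type average library sizes, rescaled to mean 1.

    The rescale is cosmetic (the adjustment formula is scale-invariant) but
    makes the values comparable across references.
    """
    vals = np.asarray(ref_library_sizes, dtype=float)
    if np.any(vals <= 0):
        raise ValidationError("library sizes must be strictly positive")
    if cell_types is None:
        cell_types = [f"type{k}" for k in range(vals.size)]
    return CellSizes(list(cell_types), vals / vals.mean())
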