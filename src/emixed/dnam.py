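"""EM deconvolution of bulk DNA methylation under a Bernoulli allocation model.

Each DNA molecule covering CpG locus ``g`` in sample ``n`` originates from a
cell type drawn from the sample's fraction vector ``theta_n``, and is
methylated with that type's signature probability ``pi[g, k]``.  Marginally
the methylated count at a locus is Binomial(coverage, ``pi[g] @ theta``).
The EM steps are closed-form:

    E-step:  psi1[g, k] = theta[k] pi[g, k]       / sum_i theta[i] pi[g, i]
             psi0[g, k] = theta[k] (1 - pi[g, k]) / sum_i theta[i] (1 - pi[g, i])
    M-step (sequencing):
             theta[k] propto sum_g psi1[g, k] * meth[g]
                           + psi0[g, k] * (cov[g] - meth[g])

For array data only beta values ``beta = meth / cov`` are observed; assuming
a large constant coverage per sample, the counts in the M-step reduce to the
beta weights, so the array update is the sequencing update with ``meth``
replaced by ``beta`` and coverage by 1.

``theta`` is a molecule-level fraction; since each cell contributes
approximately the same number of DNA copies, no cell-size correction applies
to this modality.  The signature ``pi`` is treated as fixed and known.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import Config
from .types import (
    BulkMatrix,
    CellFractions,
    FitResult,
    MethylSignature,
    ValidationError,
)

__all__ = [
    "clip_signature",
    "dnam_e_step",
    "dnam_m_step_seq",
    "dnam_m_step_array",
    "dnam_log_likelihood",
    "joint_quantile_normalize",
    "fit_dnam",
]

logger = logging.getLogger("emixed")


def clip_signature(pi, eps: float = 1e-6) -> MethylSignature:
    """Clip signature probabilities into ``[eps, 1 - eps]``.

    Reference signatures routinely contain exact 0/1; clipping keeps the
    E-step denominators strictly positive.  Accepts a DataFrame (loci x cell
    types) or an existing :class:`MethylSignature`.
    """
    if not 0 < eps < 0.5:
        raise ValidationError("clipping epsilon must lie in (0, 0.5)")
    if isinstance(pi, MethylSignature):
        loci, cell_types, vals = pi.loci, pi.cell_types, pi.values
    else:
        df = pd.DataFrame(pi)
        loci, cell_types, vals = list(df.index), list(df.columns), df.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("signature entries must lie in [0, 1] before clipping")
    return MethylSignature(list(loci), list(cell_types), np.clip(vals, eps, 1 - eps))


def dnam_e_step(
    pi: MethylSignature, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior cell-type responsibilities per locus, one sample.

    Returns ``(psi1, psi0)``, each G x K with rows on the simplex: the
    probability that a methylated (resp. unmethylated) molecule at locus ``g``
    came from each cell type under the current ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    num1 = pi.values * theta
    num0 = (1.0 - pi.values) * theta
    den1 = num1.sum(axis=1, keepdims=True)
    den0 = num0.sum(axis=1, keepdims=True)
    if np.any(den1 <= 0) or np.any(den0 <= 0):
        raise ValidationError(
            "degenerate E-step denominator; clip the signature with "
            "clip_signature before fitting"
        )
    return num1 / den1, num0 / den0


def dnam_m_step_seq(
    psi1: np.ndarray, psi0: np.ndarray, meth: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Fraction update from methylated / unmethylated molecule counts."""
    meth = np.asarray(meth, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if np.any(meth < 0) or np.any(meth > cov):
        raise ValidationError("need 0 <= methylated <= coverage at every locus")
    if cov.sum() <= 0:
        raise ValidationError("all loci have zero coverage")
    num = psi1.T @ meth + psi0.T @ (cov - meth)
    return num / num.sum()


def dnam_m_step_array(psi1: np.ndarray, psi0: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Fraction update from array beta values (constant-coverage limit)."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValidationError("beta values must lie in [0, 1]")
    num = psi1.T @ beta + psi0.T @ (1.0 - beta)
    return num / num.sum()


def dnam_log_likelihood(
    meth: np.ndarray,
    cov: np.ndarray | None,
    pi: MethylSignature,
    theta: np.ndarray,
) -> float:
    """Observed-data log-likelihood for one sample.

    Sequencing form:
    ``sum_g meth[g] log(pi[g] @ theta) + (cov[g] - meth[g]) log((1-pi[g]) @ theta)``.
    With ``cov=None``, ``meth`` is interpreted as beta values and the weights
    are ``beta`` and ``1 - beta`` (log-likelihood per unit coverage).
    """
    meth = np.asarray(meth, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if cov is None:
        w1, w0 = meth, 1.0 - meth
    else:
        cov = np.asarray(cov, dtype=float)
        w1, w0 = meth, cov - meth
    p1 = pi.values @ theta
    p0 = (1.0 - pi.values) @ theta
    if np.any((w1 > 0) & (p1 <= 0)) or np.any((w0 > 0) & (p0 <= 0)):
        raise ValidationError("zero mixture probability with positive weight")
    ll = 0.0
    m1, m0 = w1 > 0, w0 > 0
    ll += float(w1[m1] @ np.log(p1[m1]))
    ll += float(w0[m0] @ np.log(p0[m0]))
    return ll


def joint_quantile_normalize(
    ref: np.ndarray, bulk: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-normalize reference and bulk beta columns jointly.

    All K + N columns are pooled; each column's values are replaced by the
    mean of the order statistics across columns at matching ranks, so every
    output column has identical sorted values.  Ties within a column receive
    the mean of the reference quantiles they span.  Both matrices must share
    the same loci in the same order.
    """
    ref = np.asarray(ref, dtype=float)
    bulk = np.asarray(bulk, dtype=float)
    if ref.shape[0] != bulk.shape[0]:
        raise ValidationError(
            f"reference has {ref.shape[0]} loci but bulk has {bulk.shape[0]}"
        )
    X = np.hstack([ref, bulk])
    G, C = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(X, order, axis=0)
    mean_quantiles = sorted_cols.mean(axis=1)
    out = np.empty_like(X)
    for c in range(C):
        o = order[:, c]
        sv = X[o, c]
        new_group = np.r_[True, sv[1:] != sv[:-1]]
        gid = np.cumsum(new_group) - 1
        group_mean = np.bincount(gid, mean_quantiles) / np.bincount(gid)
        out[o, c] = group_mean[gid]
    return out[:, : ref.shape[1]], out[:, ref.shape[1] :]


def _fit_one_dnam(
    pi: MethylSignature,
    meth: np.ndarray,
    cov: np.ndarray | None,
    cfg: Config,
) -> tuple[np.ndarray, int, np.ndarray, bool]:
    K = pi.n_cell_types
    theta = np.full(K, 1.0 / K)
    if cov is not None:
        keep = cov > 0
        meth, cov = meth[keep], cov[keep]
        pi_vals = pi.values[keep]
        if cov.sum() <= 0:
            raise ValidationError("all loci have zero coverage in this sample")
        w1, w0 = meth, cov - meth
    else:
        pi_vals = pi.values
        w1, w0 = meth, 1.0 - meth
    trace, converged, it = [], False, 0
    one_minus = 1.0 - pi_vals
    for it in range(1, cfg.max_iter + 1):
        p1 = pi_vals @ theta
        p0 = one_minus @ theta
        # fused E+M: numerators sum_g w1_g theta_k pi_gk / p1_g + w0 analogue
        num = theta * (pi_vals.T @ (w1 / p1) + one_minus.T @ (w0 / p0))
        theta_new = num / num.sum()
        m1, m0 = w1 > 0, w0 > 0
        ll = float(w1[m1] @ np.log(pi_vals[m1] @ theta_new)) + float(
            w0[m0] @ np.log(one_minus[m0] @ theta_new)
        )
        trace.append(ll)
        delta = np.max(np.abs(theta_new - theta))
        theta = theta_new
        if delta < cfg.tol:
            converged = True
            break
    return theta, it, np.asarray(trace), converged


def fit_dnam(
    bulk: BulkMatrix, pi: MethylSignature, opts: Config | None = None
) -> FitResult:
    """Fit per-sample cell fractions from bulk DNAm data by EM.

    Accepts ``dnam_beta`` (array) or ``dnam_counts`` (sequencing) modalities.
    In array mode, joint quantile normalization of reference and bulk columns
    is applied first when ``opts.quantile_norm`` is set (the default); the
    normalized values are re-clipped to valid probability ranges.  In
    sequencing mode, loci with zero coverage in a sample are skipped for that
    sample.  Samples are fitted independently.
    """
    opts = opts or Config()
    if bulk.modality not in ("dnam_beta", "dnam_counts"):
        raise ValidationError(f"fit_dnam expects DNAm data, got {bulk.modality!r}")
    if list(bulk.features) != list(pi.loci):
        raise ValidationError(
            "bulk loci and signature loci differ; align with io.align_features first"
        )
    values = bulk.values
    if bulk.modality == "dnam_beta" and opts.quantile_norm:
        ref_qn, bulk_qn = joint_quantile_normalize(pi.values, bulk.values)
        pi = MethylSignature(
            list(pi.loci),
            list(pi.cell_types),
            np.clip(ref_qn, opts.epsilon, 1 - opts.epsilon),
        )
        values = np.clip(bulk_qn, 0.0, 1.0)
        logger.info("applied joint quantile normalization (%d columns pooled)",
                    pi.n_cell_types + bulk.n_samples)
    K = pi.n_cell_types
    N = bulk.n_samples
    thetas = np.empty((N, K))
    iters = np.empty(N, dtype=int)
    traces, conv = [], np.empty(N, dtype=bool)
    for n in range(N):
        meth = values[:, n]
        cov = None if bulk.coverage is None else bulk.coverage[:, n]
        if K == 1:
            thetas[n], iters[n], conv[n] = 1.0, 1, True
            traces.append(
                np.asarray([dnam_log_likelihood(meth, cov, pi, np.ones(1))])
            )
            continue
        thetas[n], iters[n], trace, conv[n] = _fit_one_dnam(pi, meth, cov, opts)
        traces.append(trace)
        if not conv[n]:
            logger.warning(
                "sample %r did not converge in %d iterations",
                bulk.samples[n],
                opts.max_iter,
            )
    fractions = CellFractions(list(bulk.samples), list(pi.cell_types), thetas)
    return FitResult(
        fractions=fractions, iterations=iters, loglik_trace=traces, converged=conv
    )
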