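"""Agreement metrics for comparing fraction estimates: CCC, MAE, Spearman.

Lin's concordance correlation coefficient (CCC) is the primary metric: unlike
Pearson correlation it penalizes location and scale shifts, so an estimator
that ranks samples correctly but systematically over- or under-estimates a
cell type is scored down.  Population (1/n) moments are used, matching Lin's
original definition; implementations using 1/(n-1) sample moments differ by a
factor that vanishes as n grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import CellFractions, ValidationError

__all__ = ["ccc", "mae", "spearman", "evaluate"]


def _paired(x, y, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"inputs must be equal-length 1-d vectors, got {x.shape} and {y.shape}"
        )
    if x.size < min_len:
        raise ValidationError(f"need at least {min_len} paired values, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    return x, y


def ccc(x, y, *, on_constant: str = "nan") -> float:
    """Lin's concordance correlation coefficient.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population moments.  Equals 1 only when ``y == x`` elementwise; any
    location or scale shift lowers it even at perfect correlation.

    When both inputs are constant the coefficient is undefined;
    ``on_constant`` chooses between returning ``nan`` (default) and raising.
    """
    x, y = _paired(x, y, 2)
    vx, vy = x.var(), y.var()
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        if on_constant == "raise":
            raise ValidationError("CCC undefined: both inputs are constant and equal")
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


def mae(x, y) -> float:
    """Mean absolute error, ``mean(|x - y|)``."""
    x, y = _paired(x, y, 1)
    return float(np.mean(np.abs(x - y)))


def spearman(x, y, *, on_constant: str = "nan") -> float:
    """Spearman rank correlation (ties receive average ranks)."""
    x, y = _paired(x, y, 2)
    if x.var() == 0 or y.var() == 0:
        if on_constant == "raise":
            raise ValidationError("Spearman undefined for a constant input")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def evaluate(estimates: CellFractions, truth: CellFractions) -> pd.DataFrame:
    """Per-cell-type CCC / MAE / Spearman across samples, plus their means.

    Samples and cell types are matched by label; the returned frame has one
    row per shared cell type and a final ``mean`` row holding the unweighted
    average over cell types.  Correlation metrics need at least two shared
    samples.
    """
    shared_samples = [s for s in estimates.samples if s in set(truth.samples)]
    shared_types = [c for c in estimates.cell_types if c in set(truth.cell_types)]
    if not shared_samples or not shared_types:
        raise ValidationError("no shared samples or cell types between the tables")
    if len(shared_samples) < 2:
        raise ValidationError(
            "correlation metrics need at least 2 shared samples, got "
            f"{len(shared_samples)}"
        )
    est = estimates.to_frame().loc[shared_samples, shared_types]
    tru = truth.to_frame().loc[shared_samples, shared_types]
    rows = {
        ct: {
            "ccc": ccc(est[ct], tru[ct]),
            "mae": mae(est[ct], tru[ct]),
            "spearman": spearman(est[ct], tru[ct]),
        }
        for ct in shared_types
    }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.loc["mean"] = report.mean(axis=0)
    report.index.name = "cell_type"
    return report
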