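"""Multi-omics integration of modality-specific cell-fraction estimates.

RNA-seq and DNAm bulk data from the same tissue sample share one true cell
composition, but each modality's estimate carries its own technical error.
Averaging the two estimates — by default with equal weights — has proven as
reliable as data-driven weighting while being far simpler, so the integrated
estimate here is the (weighted) mean of the per-modality fractions over the
shared cell types, renormalized to the simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import CellFractions, ValidationError

__all__ = ["MultiOmicsEstimate", "integrate"]

logger = logging.getLogger("emixed")


@dataclass
class MultiOmicsEstimate:
    """Per-modality and integrated fractions over the shared cell-type set.

    ``has_rna`` / ``has_dnam`` flag, per sample, whether that modality
    contributed; samples present in only one modality carry that modality's
    estimate unchanged (renormalized over the shared types).
    """

    integrated: CellFractions
    rna: CellFractions | None
    dnam: CellFractions | None
    has_rna: np.ndarray
    has_dnam: np.ndarray


def _renorm(values: np.ndarray) -> np.ndarray:
    sums = values.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValidationError("a sample has zero total fraction on the shared types")
    return values / sums


def integrate(
    theta_rna_cell: CellFractions,
    theta_dnam: CellFractions,
    weight_rna: float = 0.5,
) -> MultiOmicsEstimate:
    """Average RNA-derived and DNAm-derived fractions per sample.

    Parameters
    ----------
    theta_rna_cell
        Cell-size-adjusted fractions from the RNA fit (proportions of cells,
        not transcripts — pass the adjusted variant).
    theta_dnam
        Fractions from the DNAm fit.
    weight_rna
        Weight on the RNA estimate in [0, 1]; DNAm receives the complement.
        Equal weighting (0.5) is the default.

    Cell types are intersected by label (error if empty) and each output row
    is renormalized, so the result is a valid simplex even when the modality
    estimates cover different type sets.  Samples found in only one modality
    are carried through from that modality and flagged.
    """
    if not 0.0 <= weight_rna <= 1.0:
        raise ValidationError("weight_rna must lie in [0, 1]")
    types = [c for c in theta_rna_cell.cell_types if c in set(theta_dnam.cell_types)]
    if not types:
        raise ValidationError(
            f"no shared cell types between RNA ({theta_rna_cell.cell_types[:4]}) "
            f"and DNAm ({theta_dnam.cell_types[:4]}) estimates"
        )
    rna_df = theta_rna_cell.to_frame()[types]
    dnam_df = theta_dnam.to_frame()[types]
    dnam_only = [s for s in theta_dnam.samples if s not in set(theta_rna_cell.samples)]
    samples = list(theta_rna_cell.samples) + dnam_only
    if not any(s in set(theta_dnam.samples) for s in theta_rna_cell.samples):
        raise ValidationError("no shared samples between the two modality estimates")
    K = len(types)
    out = np.empty((len(samples), K))
    has_rna = np.zeros(len(samples), dtype=bool)
    has_dnam = np.zeros(len(samples), dtype=bool)
    for i, s in enumerate(samples):
        in_rna = s in rna_df.index
        in_dnam = s in dnam_df.index
        has_rna[i], has_dnam[i] = in_rna, in_dnam
        if in_rna and in_dnam:
            out[i] = weight_rna * rna_df.loc[s].to_numpy() + (
                1.0 - weight_rna
            ) * dnam_df.loc[s].to_numpy()
        elif in_rna:
            out[i] = rna_df.loc[s].to_numpy()
        else:
            out[i] = dnam_df.loc[s].to_numpy()
    n_single = int((~(has_rna & has_dnam)).sum())
    if n_single:
        logger.warning(
            "%d sample(s) present in only one modality; carrying the single "
            "estimate through",
            n_single,
        )
    integrated = CellFractions(samples, types, _renorm(out))
    return MultiOmicsEstimate(
        integrated=integrated,
        rna=CellFractions(list(rna_df.index), types, _renorm(rna_df.to_numpy())),
        dnam=CellFractions(list(dnam_df.index), types, _renorm(dnam_df.to_numpy())),
        has_rna=has_rna,
        has_dnam=has_dnam,
    )
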