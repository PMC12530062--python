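"""Typed containers for deconvolution inputs and outputs.

All containers carry explicit feature / sample / cell-type labels next to a
dense float64 array, validate their defining invariants on construction, and
convert to and from :class:`pandas.DataFrame` for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ProfileMatrix",
    "MethylSignature",
    "BulkMatrix",
    "CellSizes",
    "CellFractions",
    "FitResult",
    "MODALITIES",
]

#: Recognized bulk data modalities.
MODALITIES = ("rna_counts", "dnam_beta", "dnam_counts")

_SIMPLEX_TOL = 1e-9


class ValidationError(ValueError):
    """An input violated a structural invariant (shape, range, labels)."""


def _check_unique(labels, what: str) -> list:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        seen, dup = set(), None
        for x in labels:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return labels


@dataclass
class ProfileMatrix:
    """RNA reference profile ``A`` (genes x cell types), columns summing to 1.

    Entry ``A[i, k]`` is the probability that a transcript from a type-``k``
    cell maps to gene ``i``; each column is a distribution over genes.
    """

    features: list
    cell_types: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.features = _check_unique(self.features, "feature")
        self.cell_types = list(self.cell_types)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.features),
            len(self.cell_types),
        ):
            raise ValidationError(
                f"profile matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.cell_types)} cell types"
            )
        if len(self.cell_types) < 1:
            raise ValidationError("profile matrix needs at least one cell type")
        if np.any(self.values < 0):
            raise ValidationError("profile matrix has negative entries")
        colsums = self.values.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _SIMPLEX_TOL):
            bad = self.cell_types[int(np.argmax(np.abs(colsums - 1.0)))]
            raise ValidationError(
                f"profile column {bad!r} sums to {colsums.max():.6g}, expected 1; "
                "normalize with rna.normalize_profile first"
            )
        if np.any(self.values.sum(axis=1) == 0):
            raise ValidationError("profile matrix contains an all-zero feature row")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.cell_types)

    def subset(self, idx: np.ndarray) -> "ProfileMatrix":
        """Row subset by positional index, renormalizing columns to sum 1."""
        vals = self.values[idx]
        colsums = vals.sum(axis=0)
        if np.any(colsums <= 0):
            bad = self.cell_types[int(np.argmin(colsums))]
            raise ValidationError(
                f"cell type {bad!r} has zero total mass on the selected features"
            )
        return ProfileMatrix(
            [self.features[i] for i in idx], self.cell_types, vals / colsums
        )


@dataclass
class MethylSignature:
    """DNAm signature ``pi`` (CpG loci x cell types), probabilities in [0, 1].

    Entry ``pi[g, k]`` is the probability that a DNA molecule covering locus
    ``g`` from a type-``k`` cell is methylated.  Entries are expected to be
    clipped away from exact 0/1 (see :func:`emixed.dnam.clip_signature`) so
    the E-step denominators stay positive.
    """

    loci: list
    cell_types: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.loci = _check_unique(self.loci, "locus")
        self.cell_types = list(self.cell_types)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.loci), len(self.cell_types)):
            raise ValidationError(
                f"signature shape {self.values.shape} does not match "
                f"{len(self.loci)} loci x {len(self.cell_types)} cell types"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("methylation signature has entries outside [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.loci, columns=self.cell_types)

    def subset(self, idx: np.ndarray) -> "MethylSignature":
        return MethylSignature(
            [self.loci[i] for i in idx], self.cell_types, self.values[idx]
        )


@dataclass
class BulkMatrix:
    """Observed bulk data, features x samples, tagged with its modality.

    For ``rna_counts`` the values are RNA-seq counts ``X[i, n]``; for
    ``dnam_beta`` array beta values in [0, 1]; for ``dnam_counts`` the values
    are methylated read counts with a parallel ``coverage`` matrix of total
    molecule counts ``D[g, n]``.
    """

    features: list
    samples: list
    values: np.ndarray
    modality: str
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = _check_unique(self.features, "feature")
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"bulk matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(self.samples) < 1:
            raise ValidationError("bulk matrix needs at least one sample")
        if self.modality == "rna_counts":
            if np.any(self.values < 0):
                i, n = np.argwhere(self.values < 0)[0]
                raise ValidationError(
                    f"negative RNA count at feature {self.features[i]!r}, "
                    f"sample {self.samples[n]!r}"
                )
            if np.any(self.values.sum(axis=0) <= 0):
                n = int(np.argmin(self.values.sum(axis=0)))
                raise ValidationError(
                    f"sample {self.samples[n]!r} has zero total RNA counts"
                )
        elif self.modality == "dnam_beta":
            if np.any(self.values < 0) or np.any(self.values > 1):
                g, n = np.argwhere((self.values < 0) | (self.values > 1))[0]
                raise ValidationError(
                    f"beta value out of range [0, 1] at locus {self.features[g]!r}, "
                    f"sample {self.samples[n]!r}: {self.values[g, n]}"
                )
        else:  # dnam_counts
            if self.coverage is None:
                raise ValidationError("dnam_counts modality requires a coverage matrix")
            self.coverage = np.asarray(self.coverage, dtype=float)
            if self.coverage.shape != self.values.shape:
                raise ValidationError(
                    f"coverage shape {self.coverage.shape} does not match "
                    f"methylated-count shape {self.values.shape}"
                )
            if np.any(self.coverage < 0):
                raise ValidationError("negative coverage")
            if np.any(self.values < 0) or np.any(self.values > self.coverage):
                g, n = np.argwhere(
                    (self.values < 0) | (self.values > self.coverage)
                )[0]
                raise ValidationError(
                    f"methylated count exceeds coverage at locus "
                    f"{self.features[g]!r}, sample {self.samples[n]!r}"
                )
            for name, arr in (("methylated", self.values), ("coverage", self.coverage)):
                if np.any(arr != np.round(arr)):
                    raise ValidationError(f"{name} counts must be integer-valued")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)

    def subset(self, idx: np.ndarray) -> "BulkMatrix":
        return BulkMatrix(
            [self.features[i] for i in idx],
            self.samples,
            self.values[idx],
            self.modality,
            None if self.coverage is None else self.coverage[idx],
        )


@dataclass
class CellSizes:
    """Per-cell-type average transcript yield ``S`` (strictly positive).

    ``S[k]`` is proportional to the mean number of transcripts a single cell
    of type ``k`` contributes; only ratios matter, so values are conventionally
    rescaled to mean 1.
    """

    cell_types: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cell_types = list(self.cell_types)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_types),):
            raise ValidationError("cell sizes must be one value per cell type")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("cell sizes must be strictly positive and finite")


@dataclass
class CellFractions:
    """Per-sample cell-type fractions theta (samples x cell types, row simplex)."""

    samples: list
    cell_types: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = _check_unique(self.samples, "sample")
        self.cell_types = list(self.cell_types)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.cell_types)):
            raise ValidationError(
                f"fractions shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.cell_types)} cell types"
            )
        if np.any(self.values < -_SIMPLEX_TOL):
            raise ValidationError("cell fractions must be non-negative")
        rowsums = self.values.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _SIMPLEX_TOL):
            n = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValidationError(
                f"fractions for sample {self.samples[n]!r} sum to "
                f"{rowsums[n]:.12g}, expected 1"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.cell_types)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellFractions":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class FitResult:
    """Converged EM fit: fractions plus per-sample convergence diagnostics.

    ``loglik_trace[n]`` holds the observed-data log-likelihood after every
    iteration for sample ``n`` and is non-decreasing (EM guarantee).
    """

    fractions: CellFractions
    iterations: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    responsibilities: list | None = None
    cell_fractions: CellFractions | None = None

    def __post_init__(self) -> None:
        for n, trace in enumerate(self.loglik_trace):
            trace = np.asarray(trace, dtype=float)
            if np.any(np.diff(trace) < -1e-8 * np.maximum(1.0, np.abs(trace[:-1]))):
                raise ValidationError(
                    f"log-likelihood trace decreased for sample "
                    f"{self.fractions.samples[n]!r}"
                )
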