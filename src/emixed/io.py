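"""Reading and writing delimited matrices, feature alignment, configuration.

Matrix files are delimited text (tab by default, comma auto-detected) with one
header row of sample / cell-type labels and a first column of feature
identifiers.  Rows containing missing values are dropped with a logged count:
the EM updates have no missing-data mechanism, so silently imputing would
change the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BulkMatrix, CellFractions, ValidationError

__all__ = [
    "Config",
    "load_config",
    "read_table",
    "read_matrix",
    "read_fractions",
    "write_fractions",
    "align_features",
    "AlignmentReport",
]

logger = logging.getLogger("emixed")


@dataclass
class Config:
    """Run parameters shared by both EM fitters.

    tol: max-norm change in theta that stops the EM loop.
    max_iter: iteration cap; hitting it flags non-convergence, not an error.
    epsilon: clipping bound keeping methylation probabilities in
        [epsilon, 1 - epsilon].
    seed: seed for any stochastic step (simulation only; the fits are
        deterministic).
    quantile_norm: apply joint quantile normalization to reference and bulk
        beta values before array-mode DNAm fitting.
    """

    tol: float = 1e-6
    max_iter: int = 1000
    epsilon: float = 1e-6
    seed: int = 0
    quantile_norm: bool = True


_BOOL_TOKENS = {"true": True, "1": True, "on": True, "yes": True,
                "false": False, "0": False, "off": False, "no": False}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a flat ``key = value`` config file; every key has a default.

    Unknown keys raise; ``overrides`` (from CLI flags) take precedence over
    file values, which take precedence over defaults.
    """
    values: dict = {}
    if path is not None:
        known = {f.name: f.type for f in fields(Config)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}"
                )
            key, _, val = (t.strip() for t in line.partition("="))
            if key not in known:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "quantile_norm":
                try:
                    values[key] = _BOOL_TOKENS[val.lower()]
                except KeyError:
                    raise ValidationError(
                        f"{path}:{lineno}: cannot parse {val!r} as boolean"
                    ) from None
            elif key in ("max_iter", "seed"):
                values[key] = int(val)
            else:
                values[key] = float(val)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return Config(**values)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a labelled matrix; sniff tab vs comma from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001 - surface as validation error
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(
            f"{path}: malformed header, no sample columns after the feature column"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(
            f"{path}: non-numeric values in column(s) {non_numeric[:3]}"
        )
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a reference matrix (features x cell types) with NA rows dropped."""
    df = _read_delimited(path)
    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_na)
        df = df.dropna()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature identifier {dup!r}")
    return df


def read_matrix(
    path: str | Path,
    modality: str,
    coverage_path: str | Path | None = None,
) -> BulkMatrix:
    """Read bulk data as a validated :class:`BulkMatrix`.

    For ``dnam_counts`` two parallel files are required: ``path`` holds
    methylated counts and ``coverage_path`` total coverage, with identical
    feature and sample labels.
    """
    df = read_table(path)
    coverage = None
    if modality == "dnam_counts":
        if coverage_path is None:
            raise ValidationError("dnam_counts requires a coverage file")
        cov_df = read_table(coverage_path)
        if list(cov_df.index) != list(df.index) or list(cov_df.columns) != list(
            df.columns
        ):
            shared = df.index.intersection(cov_df.index)
            if len(shared) == 0 or list(cov_df.columns) != list(df.columns):
                raise ValidationError(
                    f"coverage file {coverage_path} does not match {path}: "
                    f"labels differ"
                )
            logger.warning(
                "restricting to %d loci shared between methylated and coverage files",
                len(shared),
            )
            df, cov_df = df.loc[shared], cov_df.loc[shared]
        coverage = cov_df.to_numpy(dtype=float)
    if modality == "rna_counts":
        vals = df.to_numpy(dtype=float)
        if np.any(vals != np.round(vals)):
            logger.warning(
                "%s: non-integer RNA values; treating as non-negative reals "
                "(the model is designed for raw counts)",
                path,
            )
    return BulkMatrix(
        list(df.index), list(df.columns), df.to_numpy(dtype=float), modality, coverage
    )


def read_fractions(path: str | Path) -> CellFractions:
    """Read a samples x cell-types fraction table written by write_fractions."""
    df = _read_delimited(path)
    return CellFractions(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_fractions(fr: CellFractions, path: str | Path) -> None:
    """Write fractions as TSV, samples as rows, at full float precision."""
    fr.to_frame().to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class AlignmentReport:
    """Bookkeeping from matching reference and bulk feature namespaces."""

    n_shared: int
    n_dropped_ref: int
    n_dropped_bulk: int

    def __str__(self) -> str:
        return (
            f"{self.n_shared} shared features "
            f"({self.n_dropped_ref} reference-only and "
            f"{self.n_dropped_bulk} bulk-only dropped)"
        )


def align_features(
    ref_features, bulk: BulkMatrix
) -> tuple[np.ndarray, np.ndarray, AlignmentReport]:
    """Intersect reference and bulk features, preserving reference order.

    Matching is by exact string identifier.  Returns positional indices into
    the reference and into the bulk (same length, same feature at each slot)
    plus a report of how many features were dropped on each side.  An empty
    intersection is an error: it almost always means the two files use
    different identifier namespaces.
    """
    ref_features = list(ref_features)
    if len(ref_features) == 0 or bulk.n_features == 0:
        raise ValidationError("cannot align empty feature lists")
    bulk_pos = {f: i for i, f in enumerate(bulk.features)}
    ref_idx, bulk_idx = [], []
    for i, f in enumerate(ref_features):
        j = bulk_pos.get(f)
        if j is not None:
            ref_idx.append(i)
            bulk_idx.append(j)
    if not ref_idx:
        raise ValidationError(
            "no shared features between reference "
            f"(e.g. {ref_features[:3]}) and bulk (e.g. {bulk.features[:3]}); "
            "check that both use the same identifier namespace"
        )
    report = AlignmentReport(
        n_shared=len(ref_idx),
        n_dropped_ref=len(ref_features) - len(ref_idx),
        n_dropped_bulk=bulk.n_features - len(bulk_idx),
    )
    logger.info("feature alignment: %s", report)
    return np.asarray(ref_idx), np.asarray(bulk_idx), report
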