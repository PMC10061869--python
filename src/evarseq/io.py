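"""Count-matrix and metadata I/O, size-factor normalization.

Count matrices are plain :class:`pandas.DataFrame` objects with gene
identifiers as the index and sample identifiers as the columns, holding
non-negative integers.  Sample metadata is a DataFrame indexed by
``sample_id`` with the columns ``donor_group``, ``dose``, ``triplet_id``,
``sex``, ``smoking_pack_years`` and ``alcohol_per_day``.

Normalization is the median-of-ratios size-factor method: for every gene
with strictly positive counts in all samples, the per-sample ratio of its
count to its geometric mean across samples is formed, and the size factor
of a sample is the median of those ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_counts",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "compute_size_factors",
    "normalize",
]

METADATA_COLUMNS = [
    "donor_group",
    "dose",
    "triplet_id",
    "sex",
    "smoking_pack_years",
    "alcohol_per_day",
]


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a counts DataFrame invariant set; return it unchanged.

    Raises ``ValueError`` on duplicate gene or sample ids, negative
    entries, or non-integer values.
    """
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s): {dup[:5]}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s): {dup[:5]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.floor(values)):
            bad = np.argwhere(values != np.floor(values))[0]
            raise ValueError(
                f"counts must be integers; found {values[bad[0], bad[1]]!r} at "
                f"gene {counts.index[bad[0]]!r}, sample {counts.columns[bad[1]]!r}"
            )
    return counts


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = None
    counts.columns = counts.columns.astype(str)
    validate_counts(counts)
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    validate_counts(counts)
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV, indexed by ``sample_id``."""
    meta = pd.read_csv(path, sep="\t", dtype={"dose": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample_id in metadata")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Only genes with strictly positive counts in every sample enter the
    reference set; geometric means are computed in log space.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = np.all(values > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has strictly positive counts in all samples; "
            "median-of-ratios size factors are undefined "
            "(pseudo-reference fallback is disabled)"
        )
    ref = values[all_positive]
    log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_gm)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    s = size_factors.reindex(counts.columns)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise ValueError(f"size factors missing for sample(s): {missing[:5]}")
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise ValueError(f"non-positive size factor for sample(s): {bad[:5]}")
    return counts / s
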