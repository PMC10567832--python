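"""Expression containers and transforms: library-size normalization, a
variance-stabilizing transform, and the Blom rank-based inverse-normal
transform.

The container tracks a ``transform_state`` tag so that each pipeline stage
can assert it is consuming data at the expected point of the chain
(raw_counts -> normalized -> vst -> blast_corrected -> blom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ExpressionMatrix",
    "TRANSFORM_STATES",
    "normalize_library_size",
    "vst",
    "blom_transform",
    "blom",
]

TRANSFORM_STATES = ("raw_counts", "normalized", "vst", "blast_corrected", "blom")

BLOM_OFFSET = 3.0 / 8.0  # classical Blom constant


class DegenerateSampleError(ValueError):
    """A sample has no usable counts (all zero)."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression matrix with a transform-state tag.

    ``values`` is a DataFrame indexed by gene identifiers with sample
    identifiers as columns.  Identifiers must be unique; raw counts must be
    non-negative and finite.
    """

    values: pd.DataFrame
    transform_state: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.transform_state == "raw_counts" and (arr < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, transform_state=state)

    def require_state(self, *states: str) -> None:
        if self.transform_state not in states:
            raise ValueError(
                f"expected transform_state in {states}, got {self.transform_state!r}"
            )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    The reference is built over genes with all-positive counts (the only
    genes with a finite geometric mean); each sample's factor is the median
    ratio of its counts to the reference over those genes.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        bad = list(counts.columns[arr.sum(axis=0) == 0])
        raise DegenerateSampleError(f"samples with all-zero counts: {bad}")
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise DegenerateSampleError("no gene has positive counts in every sample")
    log_ref = np.log(arr[all_pos]).mean(axis=1)
    log_sf = np.median(np.log(arr[all_pos]) - log_ref[:, None], axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1: keeps the counts scale, makes
    sf = np.exp(log_sf)      # normalization idempotent
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_library_size(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    counts.require_state("raw_counts", "normalized")
    sf = size_factors(counts.values)
    out = counts.values / sf
    return counts.with_values(out, "normalized")


def vst(normalized: ExpressionMatrix, prior_count: float = 1.0) -> ExpressionMatrix:
    """Variance-stabilizing transform: elementwise log2(x + prior_count).

    A shifted-log map flattens the mean-variance dependence of
    negative-binomial counts well enough for the rank- and PC-based stages
    downstream, all of which are invariant to (or robust under) monotone
    transforms.
    """
    normalized.require_state("normalized")
    if not prior_count > 0:
        raise ValueError(f"prior_count must be positive, got {prior_count}")
    out = np.log2(normalized.values + prior_count)
    return normalized.with_values(out, "vst")


def blom_transform(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform of a vector.

    Ranks (average rank for ties) are mapped through the standard-normal
    quantile of ``(r - 3/8) / (n + 1/4)``.  A constant vector has no rank
    information; it maps to all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        warnings.warn("constant vector: Blom transform returns all zeros")
        return np.zeros_like(x)
    r = rankdata(x, method="average")
    return norm.ppf((r - BLOM_OFFSET) / (x.size + 0.25))


def blom(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the Blom transform per gene across samples."""
    arr = expr.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes handled row-wise
        out = np.vstack([blom_transform(row) for row in arr])
    n_const = int((np.ptp(arr, axis=1) == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} constant genes mapped to zeros by the Blom transform")
    return replace(
        expr,
        values=pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        transform_state="blom",
    )
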