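"""Gene-set collections (GMT semantics) and per-sample enrichment scores.

Scores follow the single-sample GSVA/ssGSEA idea: within each sample, genes
are ranked by expression and a rank-weighted Kolmogorov-Smirnov random walk
is taken over the ranking; the set's score is the maximum positive plus the
maximum negative deviation of the walk (the max-deviation form).  Being
purely rank-based, scores are invariant to any strictly monotone transform
of a sample's expression values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "gene_set_scores",
    "top_variable",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; genes may repeat across sets but not within one."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path, source_tag: str | None = None) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, then genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets=sets, source_tag=source_tag or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source_tag or "na", *genes]) + "\n")


def _walk_score(in_set: np.ndarray, rank_weight: np.ndarray) -> float:
    """Max-deviation score of the weighted KS walk over one sample's ranking.

    ``in_set`` marks hit positions in ranked (descending-expression) order;
    hit steps are proportional to ``rank_weight`` (normalized over hits),
    miss steps are uniform over the complement.  Score = max(walk) + min(walk),
    in [-1, 1].
    """
    n = in_set.size
    n_hit = int(in_set.sum())
    n_miss = n - n_hit
    if n_hit == 0 or n_miss == 0:
        return 0.0
    steps = np.where(in_set, rank_weight / rank_weight[in_set].sum(), -1.0 / n_miss)
    walk = np.cumsum(steps)
    return float(walk.max() + min(walk.min(), 0.0))


def gene_set_scores(expr: ExpressionMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Per-sample enrichment score of every set (sets x samples).

    Genes absent from the matrix are dropped per set (count logged); sets
    with fewer than 2 matched genes are skipped with a warning.  A set that
    covers the whole matrix has an empty complement and scores 0 (logged).
    """
    vals = expr.values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    n_genes, n_samples = vals.shape

    # ranked (descending) order per sample; rank weight decays linearly with rank
    order = np.argsort(-vals, axis=0, kind="stable")
    rank_weight = (n_genes - np.arange(n_genes)).astype(float)

    rows: dict[str, np.ndarray] = {}
    for name, genes in sets:
        idx = [gene_index[g] for g in genes if g in gene_index]
        dropped = len(genes) - len(idx)
        if dropped:
            logger.info("set %s: %d genes absent from matrix", name, dropped)
        if len(idx) < 2:
            warnings.warn(f"set {name!r}: fewer than 2 genes matched, skipped")
            continue
        member = np.zeros(n_genes, dtype=bool)
        member[idx] = True
        if member.all():
            logger.info("set %s covers every gene: empty complement, score 0", name)
            rows[name] = np.zeros(n_samples)
            continue
        scores = np.empty(n_samples)
        for j in range(n_samples):
            scores[j] = _walk_score(member[order[:, j]], rank_weight)
        rows[name] = scores

    return pd.DataFrame(rows, index=expr.sample_ids).T


def top_variable(scores: pd.DataFrame, n_top: int) -> pd.DataFrame:
    """Rows with highest variance across samples, variance-descending order."""
    if n_top > scores.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds number of rows {scores.shape[0]}")
    variances = scores.var(axis=1, ddof=1)
    order = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    return scores.loc[order]
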