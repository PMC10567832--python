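"""Monti-style consensus clustering and response-label reassignment.

Samples are repeatedly subsampled; each subsample is cut into k groups by
hierarchical clustering (Euclidean distance, average linkage); the consensus
matrix records, for every sample pair, the fraction of co-sampled draws in
which the pair co-clustered.  Final labels come from hierarchical clustering
of 1 - consensus.  With k = 2 the clusters rename the raw bone-marrow
response: the cluster holding the majority of raw responders becomes the
consensus-clustered responder class, and every sample - including
non-evaluable ones - inherits its cluster's name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = ["ConsensusResult", "consensus_cluster", "reassign_labels"]

RESPONDER_CLASS = "BMR_CC"
NONRESPONDER_CLASS = "no-BMR_CC"


@dataclass(frozen=True)
class ConsensusResult:
    consensus_matrix: pd.DataFrame  # samples x samples, in [0,1], unit diagonal
    labels: pd.Series  # per-sample cluster id in 1..k
    k: int
    n_resamples: int
    subsample_fraction: float
    item_consensus: pd.Series  # mean within-cluster consensus per sample


def _hcluster(x: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage Euclidean clustering of rows into k flat clusters."""
    z = linkage(x, method="average", metric="euclidean")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    scores: pd.DataFrame,
    k: int = 2,
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Consensus-cluster samples (columns of ``scores``) into k groups."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    n = scores.shape[1]
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for k={k}")

    rng = np.random.default_rng(seed)
    x = scores.to_numpy(dtype=float).T  # samples x features
    n_sub = max(k, int(round(subsample_fraction * n)))

    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=n_sub, replace=False)
        lab = _hcluster(x[idx], k)
        co = (lab[:, None] == lab[None, :]).astype(float)
        together[np.ix_(idx, idx)] += co
        sampled[np.ix_(idx, idx)] += 1.0

    never = sampled == 0
    if never.any() and n_resamples > 0:
        warnings.warn(
            f"{int(never.sum() // 2)} sample pairs never co-sampled; consensus set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(never, 0.0, together / np.where(never, 1.0, sampled))
    np.fill_diagonal(consensus, 1.0)

    final = _hcluster_from_consensus(consensus, k)
    ids = scores.columns
    labels = pd.Series(final, index=ids, name="cluster")

    item = np.empty(n)
    for i in range(n):
        mates = (final == final[i]) & (np.arange(n) != i)
        item[i] = consensus[i, mates].mean() if mates.any() else 1.0

    return ConsensusResult(
        consensus_matrix=pd.DataFrame(consensus, index=ids, columns=ids),
        labels=labels,
        k=k,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        item_consensus=pd.Series(item, index=ids, name="item_consensus"),
    )


def _hcluster_from_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for pdist
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def reassign_labels(
    result: ConsensusResult,
    raw_labels: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """Rename k=2 clusters by majority raw response and relabel all samples.

    ``raw_labels`` holds {"BMR", "no-BMR", "NE"} per sample.  The cluster
    containing the majority of raw "BMR" samples becomes ``BMR_CC``; a tie is
    broken toward the cluster whose raw-BMR members have higher mean item
    consensus.  Returns the per-sample consensus labels and a mapping table
    (sample, raw label, cluster, consensus label).
    """
    if result.k != 2:
        raise ValueError("label reassignment is defined for k=2 clusterings")
    raw = raw_labels.reindex(result.labels.index)
    if raw.isna().any():
        raise ValueError("raw_labels missing for some clustered samples")
    bad = set(raw.unique()) - {"BMR", "no-BMR", "NE"}
    if bad:
        raise ValueError(f"unexpected raw labels: {sorted(bad)}")

    is_bmr = raw == "BMR"
    counts = {c: int((result.labels[is_bmr] == c).sum()) for c in (1, 2)}
    if counts[1] != counts[2]:
        responder_cluster = max(counts, key=counts.get)
    else:
        mean_ic = {
            c: result.item_consensus[is_bmr & (result.labels == c)].mean() for c in (1, 2)
        }
        responder_cluster = max(mean_ic, key=lambda c: (np.nan_to_num(mean_ic[c], nan=-1.0)))
        warnings.warn(
            "tie in raw-BMR majority vote; broke toward cluster "
            f"{responder_cluster} by mean item consensus"
        )

    new = result.labels.map(
        lambda c: RESPONDER_CLASS if c == responder_cluster else NONRESPONDER_CLASS
    ).rename("consensus_label")
    mapping = pd.DataFrame(
        {"raw_label": raw, "cluster": result.labels, "consensus_label": new}
    )
    return new, mapping
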