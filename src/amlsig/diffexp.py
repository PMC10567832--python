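"""Differential expression and preranked gene-set enrichment.

The two-group comparison uses a moderated t-statistic: per-gene residual
variances are shrunk toward a common prior by empirical Bayes, with the
prior degrees of freedom d0 and prior variance s0^2 fitted by moment
matching on the distribution of log sample variances across genes.  Genes
are ranked by the signed significance score log2FC x -log10(p), and a
weighted-KS preranked GSEA with gene-label permutation produces per-set
enrichment scores, permutation p-values (BH-adjusted across sets) and
leading-edge gene lists.  The modeling feature pool is the union of
significant leading edges, filtered to an external gene universe and
truncated at the knee of the absolute-score decay curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection
from .knee import knee_index
from .preprocess import ExpressionMatrix

__all__ = ["moderated_t", "preranked_gsea", "build_feature_pool", "EmptyPoolError"]

logger = logging.getLogger(__name__)


class EmptyPoolError(RuntimeError):
    """No leading-edge gene survived significance and universe filtering."""


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 near 0
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Under the hierarchical model, z = log(s^2) has mean
    log(s0^2) + digamma(df/2) - log(df/2) - (digamma(d0/2) - log(d0/2)) and
    excess variance trigamma(d0/2) beyond the sampling term trigamma(df/2);
    inverting the trigamma recovers d0.  Non-positive excess variance means
    the gene variances are as concentrated as a single variance would allow:
    d0 = inf (complete shrinkage to s0^2).
    """
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(_trigamma(df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    expr: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series | np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t between two groups of samples.

    ``groups`` is binary (the positive class defines the fold-change sign).
    Returns a DataFrame indexed by gene with columns ``log2_fc``,
    ``moderated_t``, ``p_value``, ``signed_score``, sorted by signed score
    descending (ready for preranked GSEA).  ``prior_df`` overrides the
    estimated d0; 0 recovers the ordinary two-sample t.
    """
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    y = np.asarray(groups)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two groups, got {classes}")
    pos, neg = classes[1], classes[0]
    m1 = vals.loc[:, y == pos].to_numpy(dtype=float)
    m0 = vals.loc[:, y == neg].to_numpy(dtype=float)
    n1, n0 = m1.shape[1], m0.shape[1]
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per group")

    diff = m1.mean(axis=1) - m0.mean(axis=1)
    df_resid = n1 + n0 - 2
    ss = ((m1 - m1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (m0 - m0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    positive = s2 > 0
    if prior_df is None:
        if positive.sum() < 2:
            raise ValueError("too few genes with positive variance to fit the prior")
        d0, s0_2 = fit_variance_prior(s2[positive], df_resid)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        if positive.sum() < 2:
            raise ValueError("too few genes with positive variance to fit the prior")
        _, s0_2 = fit_variance_prior(s2[positive], df_resid)
        d0 = float(prior_df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_stat), df=df_total)

    # genes flat in both groups carry no evidence
    degenerate = (~positive) & (diff == 0)
    if degenerate.any():
        logger.info("%d genes constant in both groups: t=0, p=1", int(degenerate.sum()))
        t_stat = np.where(degenerate, 0.0, t_stat)
        p = np.where(degenerate, 1.0, p)

    p = np.clip(p, np.finfo(float).tiny, 1.0)
    signed = diff * (-np.log10(p))
    out = pd.DataFrame(
        {
            "log2_fc": diff,
            "moderated_t": t_stat,
            "p_value": p,
            "signed_score": signed,
        },
        index=vals.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    return out.sort_values("signed_score", ascending=False, kind="stable")


def _enrichment_score(
    abs_scores: np.ndarray, hit_mask: np.ndarray
) -> tuple[float, int]:
    """Weighted-KS enrichment score and peak position on a ranked list.

    Hit increments are proportional to the absolute ranking score (weight
    exponent 1), miss decrements uniform; the ES is the running-sum value of
    largest magnitude, its position the peak index.
    """
    n = abs_scores.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    if n_hit == 0 or n_miss == 0:
        raise ValueError("set must hit some but not all genes of the ranked list")
    hit_w = abs_scores * hit_mask
    total = hit_w.sum()
    if total == 0:  # all hits carry score 0: fall back to unweighted steps
        hit_w = hit_mask.astype(float)
        total = float(n_hit)
    steps = hit_w / total - (~hit_mask) / n_miss
    walk = np.cumsum(steps)
    peak = int(np.argmax(np.abs(walk)))
    return float(walk[peak]), peak


@dataclass(frozen=True)
class GseaResult:
    """Per-set preranked GSEA results plus the run's permutation settings."""

    table: pd.DataFrame  # index: set name; es, nes, p_value, p_adjusted, n_genes
    leading_edges: dict[str, list[str]]
    n_permutations: int
    seed: int | None


def preranked_gsea(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Preranked GSEA over a signed-score-sorted gene list.

    Significance is assessed by gene-label permutation: for each set, the
    hit positions are redrawn uniformly ``n_permutations`` times and the
    observed ES compared with the same-sign permutation tail.  BH adjustment
    is applied across analyzed sets.
    """
    if not ranked["signed_score"].is_monotonic_decreasing:
        ranked = ranked.sort_values("signed_score", ascending=False, kind="stable")
    genes = ranked.index.to_numpy()
    abs_scores = np.abs(ranked["signed_score"].to_numpy(dtype=float))
    n = genes.size
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    names, ess, nes_list, pvals, n_matched = [], [], [], [], []
    leading: dict[str, list[str]] = {}
    for name, members in sets:
        idx = np.array([pos_of[g] for g in members if g in pos_of], dtype=int)
        if idx.size < 2:
            warnings.warn(f"set {name!r}: fewer than 2 genes in the ranked list, skipped")
            continue
        if idx.size == n:
            warnings.warn(f"set {name!r} covers the whole ranked list, skipped")
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, peak = _enrichment_score(abs_scores, mask)

        if es >= 0:
            le = [g for g in genes[: peak + 1] if pos_of[g] in set(idx)]
        else:
            le = [g for g in genes[peak:] if pos_of[g] in set(idx)]

        perm_es = np.empty(n_permutations)
        for b in range(n_permutations):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=idx.size, replace=False)] = True
            perm_es[b], _ = _enrichment_score(abs_scores, pmask)
        # significance against the same-sign permutation tail (the standard
        # convention: each tail is referred to its own null mass, keeping the
        # p-value uniform under the null)
        if es >= 0:
            same = perm_es[perm_es >= 0]
            p = (1.0 + (same >= es).sum()) / (1.0 + same.size)
        else:
            same = perm_es[perm_es < 0]
            p = (1.0 + (same <= es).sum()) / (1.0 + same.size)
        nonzero = same[same != 0]
        denom = np.abs(nonzero).mean() if nonzero.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan

        names.append(name)
        ess.append(es)
        nes_list.append(nes)
        pvals.append(p)
        n_matched.append(idx.size)
        leading[name] = le

    if not names:
        raise ValueError("no analyzable gene set")
    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "es": ess,
            "nes": nes_list,
            "p_value": pvals,
            "p_adjusted": padj,
            "n_genes": n_matched,
        },
        index=pd.Index(names, name="set"),
    )
    return GseaResult(table, leading, n_permutations, seed)


def build_feature_pool(
    results: GseaResult,
    ranked: pd.DataFrame,
    external_universe: list[str] | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Modeling feature pool from significant leading edges.

    Union of leading-edge genes over sets with BH-adjusted p < alpha,
    intersected with ``external_universe`` (genes quantified in the external
    cohort the signature will be applied to), ranked by absolute signed
    score and truncated at the knee of the score decay curve.
    """
    sig_sets = results.table.index[results.table["p_adjusted"] < alpha]
    pool: set[str] = set()
    for name in sig_sets:
        pool.update(results.leading_edges[name])
    if not pool:
        raise EmptyPoolError(
            f"no leading-edge genes at adjusted p < {alpha} "
            f"({len(results.table)} sets analyzed, min adjusted p = "
            f"{results.table['p_adjusted'].min():.3g})"
        )
    if external_universe is not None:
        kept = pool & set(external_universe)
        logger.info("universe filter: %d of %d genes retained", len(kept), len(pool))
        pool = kept
        if not pool:
            raise EmptyPoolError("universe filter removed every leading-edge gene")

    abs_scores = ranked.loc[sorted(pool)]["signed_score"].abs()
    ordered = abs_scores.sort_values(ascending=False, kind="stable")
    if len(ordered) <= 2:
        return list(ordered.index)
    idx, dist = knee_index(ordered.to_numpy())
    cutoff = len(ordered) if dist <= 0 else idx + 1
    return list(ordered.index[:cutoff])
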