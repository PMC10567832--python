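"""Exact conditional inference on 2x2 response tables.

Conditioning on both margins of a 2x2 table leaves a single free cell ``a``
whose distribution is noncentral (Fisher) hypergeometric with odds-ratio
parameter psi.  This module provides the Fisher exact test (probability-mass
two-sided rule), the conditional maximum-likelihood estimate of psi (the
value under which the conditional expectation of ``a`` equals its observed
value), and exact two-sided confidence limits obtained by inverting the
one-sided conditional tail tests at alpha/2 per side.

The CMLE is the natural companion of the Fisher test for small trial
cohorts: it shrinks the crude odds ratio ``ad/bc`` toward 1 and remains
defined (as 0 or infinity) when a boundary cell is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContingencyTable",
    "ExactResult",
    "fisher_exact",
    "cmle_odds_ratio",
    "tabulate_responses",
]

# relative tolerance when comparing hypergeometric point probabilities in the
# two-sided rule; guards against ties lost to floating-point rounding
_P_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of counts: (exposed, unexposed) x (responder, non-responder).

    Cell layout::

        a  b      exposed responders, exposed non-responders
        c  d      unexposed responders, unexposed non-responders
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def support(self) -> tuple[int, int]:
        """Attainable range of cell ``a`` given the margins."""
        r1 = self.a + self.b
        c1 = self.a + self.c
        return (max(0, r1 + c1 - self.n), min(r1, c1))

    @property
    def sample_odds_ratio(self) -> float:
        """Crude odds ratio ad/bc (inf when bc == 0 and ad > 0, nan for 0/0)."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return np.nan if num == 0 else np.inf
        return num / den

    def transpose_exposure(self) -> "ContingencyTable":
        """Swap exposure columns within rows: (a,b;c,d) -> (b,a;d,c)."""
        return ContingencyTable(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class ExactResult:
    """Conditional-MLE odds ratio with exact confidence limits and Fisher p."""

    cmle_or: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    alpha: float
    table: ContingencyTable = field(repr=False)


def _log_weights(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of cell ``a`` and log central-hypergeometric weights."""
    r1, _ = table.row_margins
    c1, _ = table.col_margins
    lo, hi = table.support
    ks = np.arange(lo, hi + 1)

    def logc(n: int, k: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    lw = logc(r1, ks) + logc(table.n - r1, c1 - ks)
    return ks, lw


def _conditional_pmf(ks: np.ndarray, lw0: np.ndarray, log_psi: float) -> np.ndarray:
    lw = lw0 + ks * log_psi
    return np.exp(lw - logsumexp(lw))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value, probability-mass criterion.

    Sums the central hypergeometric probabilities of every table sharing the
    observed margins whose probability does not exceed that of the observed
    table (up to a small relative tolerance).  A zero margin makes the table
    the only attainable one; p = 1 by convention.
    """
    if 0 in table.row_margins or 0 in table.col_margins:
        warnings.warn("zero margin: table is degenerate, p = 1 by convention")
        return 1.0
    ks, lw0 = _log_weights(table)
    pmf = _conditional_pmf(ks, lw0, 0.0)
    p_obs = pmf[ks == table.a][0]
    return float(min(1.0, pmf[pmf <= p_obs * _P_REL_TOL].sum()))


def _solve_log_psi(f, lo: float = -50.0, hi: float = 50.0) -> float:
    return brentq(f, lo, hi, xtol=1e-12)


def cmle_odds_ratio(table: ContingencyTable, alpha: float = 0.05) -> ExactResult:
    """Conditional-MLE odds ratio with exact (1 - alpha) confidence limits.

    The point estimate solves ``E[A | margins, psi] = a`` by bisection on
    log psi; it is 0 (resp. inf) when ``a`` sits at the bottom (resp. top)
    of its conditional support.  The limits invert the one-sided exact tail
    probabilities at alpha/2 per side, with the same boundary conventions.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    lo, hi = table.support
    if lo == hi:
        raise ValueError("degenerate support: only one table attainable, odds ratio undefined")
    ks, lw0 = _log_weights(table)
    a = table.a

    def cond_mean(log_psi: float) -> float:
        return float(_conditional_pmf(ks, lw0, log_psi) @ ks)

    if a == lo:
        psi_hat = 0.0
    elif a == hi:
        psi_hat = np.inf
    else:
        psi_hat = float(np.exp(_solve_log_psi(lambda lp: cond_mean(lp) - a)))

    def p_le(log_psi: float) -> float:  # P(A <= a | psi)
        return float(_conditional_pmf(ks, lw0, log_psi)[ks <= a].sum())

    def p_ge(log_psi: float) -> float:  # P(A >= a | psi)
        return float(_conditional_pmf(ks, lw0, log_psi)[ks >= a].sum())

    half = alpha / 2.0
    ci_low = 0.0 if a == lo else float(np.exp(_solve_log_psi(lambda lp: p_ge(lp) - half)))
    ci_high = np.inf if a == hi else float(np.exp(_solve_log_psi(lambda lp: p_le(lp) - half)))

    return ExactResult(
        cmle_or=psi_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=fisher_exact(table),
        alpha=alpha,
        table=table,
    )


# response definitions: label sets counted as a response
_RESPONSE_LABELS = {
    "crcri": {"CR", "CRi"},
    "orr": {"CR", "CRi", "MLFS", "PR"},
}


def tabulate_responses(
    metadata: pd.DataFrame,
    response_def: str,
    stratifier: str,
) -> ContingencyTable:
    """Count evaluable patients into a 2x2 response-by-stratum table.

    Parameters
    ----------
    metadata
        Per-patient table.  Requires an ``evaluable`` boolean column and the
        ``stratifier`` boolean column.  Response is taken from a ``response``
        label column for ``crcri``/``orr``; bone-marrow response (``bmr``) is
        computed as a >= 50% relative drop from ``baseline_blasts`` to
        ``nadir_blasts`` when both columns are present, else read from a
        boolean ``bmr`` column.
    response_def
        One of ``crcri``, ``orr``, ``bmr``.
    stratifier
        Name of the boolean exposure column (e.g. ``prior_hma``,
        ``mut_srsf2_sf3b1``).
    """
    if response_def not in {"crcri", "orr", "bmr"}:
        raise ValueError(f"unknown response definition {response_def!r}")
    if stratifier not in metadata.columns:
        raise KeyError(f"stratifier column {stratifier!r} not in metadata")
    if "evaluable" not in metadata.columns:
        raise KeyError("metadata must contain an 'evaluable' column")

    df = metadata[metadata["evaluable"].astype(bool)].copy()

    if response_def == "bmr":
        if {"baseline_blasts", "nadir_blasts"}.issubset(df.columns):
            base = df["baseline_blasts"].astype(float)
            nadir = df["nadir_blasts"].astype(float)
            responder = (base - nadir) >= 0.5 * base  # >=50% relative drop
        elif "bmr" in df.columns:
            responder = df["bmr"].astype(bool)
        else:
            raise KeyError("need baseline_blasts/nadir_blasts or a 'bmr' column")
    else:
        if "response" not in df.columns:
            raise KeyError("metadata must contain a 'response' label column")
        missing = df["response"].isna()
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} evaluable patients lack a response label; excluded: "
                f"{list(df.index[missing])}"
            )
            df = df[~missing]
        responder = df["response"].isin(_RESPONSE_LABELS[response_def])

    exposed = df.loc[responder.index, stratifier].astype(bool)
    a = int((exposed & responder).sum())
    b = int((exposed & ~responder).sum())
    c = int((~exposed & responder).sum())
    d = int((~exposed & ~responder).sum())
    return ContingencyTable(a, b, c, d)
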