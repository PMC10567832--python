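"""Removal of expression variance driven by circulating blast fraction.

Peripheral-blood expression from AML patients mixes leukemic blasts with
normal leukocytes in sample-specific proportions, so the leading principal
components of the count matrix often track the blast percentage rather than
biology of interest.  The correction here scores every PC by the product of
(i) the coefficient of determination R^2 between the per-sample PC score
and %peripheral blasts and (ii) the percent of overall expression variance
the PC explains (POV).  PCs are sorted by this weighted POV, the knee of
the cumulative curve picks how many to drop, and the matrix is
reconstructed without them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knee import cumulative_knee_count
from .preprocess import ExpressionMatrix

__all__ = ["BlastCorrectionResult", "correct_for_blasts"]

_KNEE_TOL = 1e-12  # below this chord distance the weighted-POV curve is flat


@dataclass(frozen=True)
class BlastCorrectionResult:
    corrected: ExpressionMatrix
    per_pc_r2: np.ndarray
    per_pc_pov: np.ndarray  # percent, sums to ~100 over all PCs
    weighted_pov: np.ndarray
    removed_pcs: list[int]  # original PC indices, strongest first
    inflection_index: int  # position on the sorted cumulative curve

    def report(self) -> pd.DataFrame:
        """Per-PC table: R^2, POV, weighted POV, removed flag."""
        k = len(self.per_pc_r2)
        return pd.DataFrame(
            {
                "pc": np.arange(1, k + 1),
                "r2": self.per_pc_r2,
                "pov": self.per_pc_pov,
                "weighted_pov": self.weighted_pov,
                "removed": [i in self.removed_pcs for i in range(k)],
            }
        )


def _pc_scores_r2(scores: np.ndarray, covariate: np.ndarray) -> float:
    """Squared Pearson correlation; 0 for a zero-variance PC score."""
    if np.ptp(scores) == 0 or np.ptp(covariate) == 0:
        return 0.0
    r = np.corrcoef(scores, covariate)[0, 1]
    return float(r * r)


def correct_for_blasts(
    expr: ExpressionMatrix,
    blast_pct: np.ndarray,
) -> BlastCorrectionResult:
    """Back-transform expression excluding the PCs most tied to %blasts.

    Genes are mean-centered and the sample-space PCA taken by SVD.  Per PC,
    R^2 is the squared correlation of its per-sample score with the blast
    fraction, weighted POV is R^2 x POV, and the number of PCs removed is
    the knee (maximum perpendicular distance to the chord) of the cumulative
    sorted weighted-POV curve.  Accepts blast values on either the [0,1] or
    the [0,100] scale.
    """
    expr.require_state("vst")
    blast = np.asarray(blast_pct, dtype=float)
    if blast.shape != (expr.n_samples,):
        raise ValueError(
            f"blast_pct must have one value per sample ({expr.n_samples}), got {blast.shape}"
        )
    if not np.isfinite(blast).all() or blast.min() < 0:
        raise ValueError("blast fractions must be finite and non-negative")
    if blast.max() > 1.0:  # percent scale
        if blast.max() > 100.0:
            raise ValueError("blast values exceed 100%")
        blast = blast / 100.0
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for PC-based correction")

    x = expr.values.to_numpy(dtype=float)
    gene_means = x.mean(axis=1, keepdims=True)
    xc = x - gene_means

    # thin SVD: xc = U S Vt; per-sample scores of PC k are S[k] * Vt[k]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pov = 100.0 * s**2 / max(s @ s, np.finfo(float).tiny)
    scores = s[:, None] * vt

    if np.ptp(blast) == 0:
        warnings.warn("constant blast fraction: no PC is removable, returning input unchanged")
        corrected = expr.with_values(expr.values.copy(), "blast_corrected")
        zeros = np.zeros_like(s)
        return BlastCorrectionResult(corrected, zeros, pov, zeros, [], 0)

    r2 = np.array([_pc_scores_r2(scores[k], blast) for k in range(len(s))])
    weighted = r2 * pov

    order = np.argsort(weighted)[::-1]  # strongest association first
    count, dist = cumulative_knee_count(weighted[order])
    if dist < _KNEE_TOL or count == 0:
        warnings.warn("flat weighted-POV curve: no knee detected, removing no PCs")
        removed: list[int] = []
        count = 0
    else:
        removed = [int(i) for i in order[:count]]

    if removed:
        rm = np.array(removed)
        xc = xc - (u[:, rm] * s[rm]) @ vt[rm]
    out = pd.DataFrame(xc + gene_means, index=expr.gene_ids, columns=expr.sample_ids)
    corrected = expr.with_values(out, "blast_corrected")
    return BlastCorrectionResult(corrected, r2, pov, weighted, removed, count)
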