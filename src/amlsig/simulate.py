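"""Synthetic trial data with the structure the pipeline assumes.

The generator emulates the correlative-study inputs: a bulk RNA-seq count
matrix from peripheral blood of a small AML cohort (negative-binomial
counts, log-linear means), a per-sample circulating-blast fraction loading
onto a designated block of confounded genes, two latent response classes
separated in a small set of signature genes, raw bone-marrow-response
labels with a few non-evaluable samples, gene-set collections that include
a signature-bearing set, and a binary mutation matrix in which planted
genes (an "SRSF2"-like positive driver among them) track the continuous
response probability.

Defaults mirror the cohort that motivated the design: 32 RNA-seq samples,
a 53% responder fraction, blast fractions spanning a few percent to near
1, a 10-gene signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .preprocess import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_mutations",
    "simulate_gene_sets",
    "InvalidConfigError",
]


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


def _default_mutation_genes() -> dict[str, tuple[float, float]]:
    # (probability at response probability 0, probability at 1)
    return {
        "SRSF2": (0.05, 0.55),  # planted positive driver
        "SF3B1": (0.03, 0.20),
        "TP53": (0.20, 0.20),  # null: class-independent
        "ASXL1": (0.22, 0.22),  # null
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; all defaults are the study conditions."""

    n_samples: int = 32
    n_genes: int = 1000
    n_gene_sets: int = 40
    blast_fractions: np.ndarray | None = None  # default: Beta(1.3, 3.5) draws
    responder_fraction: float = 17 / 32
    n_signature_genes: int = 10
    signature_effect: float = 1.5  # log2-scale mean shift between classes
    blast_effect: float = 1.5  # log2-scale loading of blast fraction
    n_confounded_genes: int | None = None  # default: 30% of the gene universe
    mutation_genes: dict[str, tuple[float, float]] = field(
        default_factory=_default_mutation_genes
    )
    n_null_mutation_genes: int = 20
    dispersion: float = 0.1  # negative-binomial; 0 -> Poisson
    ne_fraction: float = 0.1  # non-evaluable samples among the cohort
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_gene_sets", "n_signature_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidConfigError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("responder_fraction", "ne_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("signature_effect", "blast_effect", "dispersion"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidConfigError(f"{name} must be finite, got {v!r}")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")
        if self.n_confounded_genes is None:
            object.__setattr__(self, "n_confounded_genes", int(round(0.3 * self.n_genes)))
        if self.n_confounded_genes < 0 or self.n_confounded_genes > self.n_genes:
            raise InvalidConfigError("n_confounded_genes must lie in [0, n_genes]")
        if self.n_signature_genes + self.n_confounded_genes > self.n_genes:
            raise InvalidConfigError("signature and confounded blocks exceed the gene universe")
        if self.blast_fractions is not None:
            bf = np.asarray(self.blast_fractions, dtype=float)
            if bf.shape != (self.n_samples,):
                raise InvalidConfigError("blast_fractions must have one value per sample")
            if not np.isfinite(bf).all() or bf.min() < 0 or bf.max() > 1:
                raise InvalidConfigError("blast_fractions must lie in [0, 1]")
        for gene, (p0, p1) in self.mutation_genes.items():
            if not (np.isfinite(p0) and np.isfinite(p1) and 0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise InvalidConfigError(f"mutation probabilities for {gene} must lie in [0, 1]")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the count matrix and per-sample metadata.

    Log2 gene means are baseline + blast_effect x blast fraction on the
    confounded block + (+/-) signature_effect on the signature block for
    responders; counts are negative-binomial around those means.  Metadata
    carries the blast percentage, true class, raw bone-marrow-response
    label (with non-evaluable samples), and planted mutation flags; the
    identities of signature and confounded genes ride along in
    ``metadata.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    if config.blast_fractions is not None:
        blast = np.asarray(config.blast_fractions, dtype=float)
    else:
        blast = rng.beta(1.3, 3.5, size=n)

    n_resp = int(round(config.responder_fraction * n))
    responder = np.zeros(n, dtype=bool)
    responder[rng.choice(n, size=n_resp, replace=False)] = True

    gene_ids = [f"G{i:04d}" for i in range(g)]
    sample_ids = [f"S{j:02d}" for j in range(n)]

    picks = rng.choice(g, size=config.n_confounded_genes + config.n_signature_genes, replace=False)
    confounded = picks[: config.n_confounded_genes]
    signature = picks[config.n_confounded_genes :]
    sig_sign = rng.choice([-1.0, 1.0], size=config.n_signature_genes)

    base = rng.uniform(2.0, 9.0, size=g)
    # per-gene log2-scale noise SD of NB counts (delta method):
    # var(log2 X) ~ (1/mu + dispersion) / ln(2)^2; the signature effect is a
    # standardized shift, i.e. expressed in units of this SD
    sd_log2 = np.sqrt(1.0 / np.exp2(base) + config.dispersion) / np.log(2.0)
    log2_mu = np.tile(base[:, None], (1, n))
    log2_mu[confounded] += config.blast_effect * blast[None, :]
    log2_mu[signature] += (
        config.signature_effect
        * sd_log2[signature, None]
        * sig_sign[:, None]
        * responder[None, :].astype(float)
    )
    counts = _nb_draw(rng, np.exp2(log2_mu), config.dispersion)

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), "raw_counts"
    )

    n_ne = int(round(config.ne_fraction * n))
    ne = np.zeros(n, dtype=bool)
    if n_ne:
        ne[rng.choice(n, size=n_ne, replace=False)] = True
    raw_label = np.where(ne, "NE", np.where(responder, "BMR", "no-BMR"))

    meta = pd.DataFrame(
        {
            "blast_pct": 100.0 * blast,
            "true_class": np.where(responder, "responder", "non-responder"),
            "raw_label": raw_label,
            "bmr": raw_label == "BMR",
            "evaluable": ~ne,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for gene, (p0, p1) in config.mutation_genes.items():
        p = p0 + (p1 - p0) * responder.astype(float)
        meta[f"mut_{gene}"] = rng.random(n) < p
    meta.attrs["signature_genes"] = [gene_ids[i] for i in signature]
    meta.attrs["signature_signs"] = sig_sign.tolist()
    meta.attrs["confounded_genes"] = [gene_ids[i] for i in confounded]
    return expr, meta


def simulate_mutations(
    config: SimulationConfig,
    true_probability: pd.Series,
) -> pd.DataFrame:
    """Binary sample x gene mutation matrix tied to a response probability.

    Planted genes interpolate their per-class mutation probabilities along
    each sample's continuous response probability; null genes mutate at a
    class-independent rate; one guaranteed rare gene (expected count 1)
    exercises the minimum-recurrence filter downstream.
    """
    prob = np.asarray(true_probability, dtype=float)
    if not np.isfinite(prob).all() or prob.min() < 0 or prob.max() > 1:
        raise InvalidConfigError("true_probability values must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    n = prob.size
    cols: dict[str, np.ndarray] = {}
    for gene, (p0, p1) in config.mutation_genes.items():
        cols[gene] = (rng.random(n) < p0 + (p1 - p0) * prob).astype(int)
    for i in range(config.n_null_mutation_genes):
        rate = rng.uniform(0.03, 0.15)
        cols[f"NULL{i:02d}"] = (rng.random(n) < rate).astype(int)
    cols["RARE1"] = (rng.random(n) < 1.0 / n).astype(int)
    return pd.DataFrame(cols, index=true_probability.index)


def simulate_gene_sets(
    config: SimulationConfig,
    gene_ids: list[str],
    signature_genes: list[str] | None = None,
    signature_signs: list[float] | None = None,
) -> GeneSetCollection:
    """Random gene sets, optionally seeding sets with the signature genes.

    Signature genes enter as coordinately regulated sets - split by effect
    direction when ``signature_signs`` is given, since a set mixing up- and
    down-shifted genes cancels in any rank-walk statistic - so that both the
    per-sample scores and preranked GSEA can see the planted classes.  The
    remaining sets are uniform draws from the universe.
    """
    rng = np.random.default_rng(config.seed + 2)
    universe = list(gene_ids)
    sets: dict[str, list[str]] = {}
    start = 0
    if signature_genes and signature_signs is not None:
        up = [g for g, s in zip(signature_genes, signature_signs) if s > 0]
        down = [g for g, s in zip(signature_genes, signature_signs) if s < 0]
        # curated collections are redundant: the same program is reported by
        # many overlapping sets, so plant several partial sets per direction
        n_variants = max(1, config.n_gene_sets // 10)
        background = [g for g in universe if g not in set(signature_genes)]
        for tag, members in (("UP", up), ("DOWN", down)):
            if len(members) < 2:
                continue
            sets[f"SIGNATURE_{tag}"] = list(members)
            start += 1
            for i in range(n_variants):
                take = max(2, int(np.ceil(0.7 * len(members))))
                core = [members[j] for j in rng.choice(len(members), size=take, replace=False)]
                pad = [background[j] for j in rng.choice(len(background), size=3, replace=False)]
                sets[f"SIGNATURE_{tag}_V{i}"] = core + pad
                start += 1
    elif signature_genes:
        extra = [g for g in universe if g not in set(signature_genes)]
        pad = rng.choice(len(extra), size=min(10, len(extra)), replace=False)
        sets["SIGNATURE_SET"] = list(signature_genes) + [extra[i] for i in pad]
        start = 1
    for i in range(start, config.n_gene_sets):
        size = int(rng.integers(10, min(51, len(universe) + 1)))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{i:03d}"] = [universe[j] for j in members]
    return GeneSetCollection(sets=sets, source_tag="synthetic")
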