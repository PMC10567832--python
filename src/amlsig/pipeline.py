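"""End-to-end pipeline orchestration on the synthetic cohort.

Stage order follows the analysis design: normalize -> variance-stabilize ->
blast-correct -> per-sample gene-set scores -> consensus-cluster response
labels -> moderated t + preranked GSEA -> feature pool -> Blom transform ->
nested boosted ensemble -> predict -> mutation association -> exact 2x2
clinical statistics.  One global seed is expanded deterministically into
per-stage seeds; every run writes its resolved configuration and a
machine-readable manifest next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blastcorrect import correct_for_blasts
from .cluster import RESPONDER_CLASS, consensus_cluster, reassign_labels
from .diffexp import build_feature_pool, moderated_t, preranked_gsea
from .ensemble import (
    NestedSplitPlan,
    feature_selection_round,
    fit_final_ensemble,
    make_split_plan,
    predict,
    tune_hyperparameters,
)
from .exact2x2 import cmle_odds_ratio, tabulate_responses
from .genesets import gene_set_scores, top_variable, write_gmt
from .io import (
    write_expression_tsv,
    write_metadata_tsv,
    write_mutations_long,
)
from .mutassoc import (
    filter_by_frequency,
    group_test,
    select_by_boosting,
    select_by_elastic_net,
    summarize_ols,
)
from .preprocess import blom, normalize_library_size, vst
from .simulate import SimulationConfig, simulate_counts, simulate_gene_sets, simulate_mutations

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGE_NAMES = [
    "simulate",
    "normalize",
    "vst",
    "blast_correction",
    "gene_set_scores",
    "consensus_clustering",
    "differential_enrichment",
    "feature_pool",
    "signature_ensemble",
    "predict",
    "mutation_association",
    "clinical_stats",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All per-stage parameters; defaults mirror the full-scale analysis."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    vst_prior_count: float = 1.0
    do_blast_correction: bool = True
    n_top_scores: int = 1345
    k: int = 2
    consensus_resamples: int = 1000
    subsample_fraction: float = 0.8
    gsea_permutations: int = 1000
    alpha: float = 0.05
    plan: NestedSplitPlan = field(default_factory=NestedSplitPlan)
    tuning_grid: dict | None = None
    do_mutation_association: bool = True
    min_mutation_count: int = 3
    elastic_net_mixing: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"unserializable {type(obj)}")

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        if raw.get("sim"):
            sim = dict(raw["sim"])
            if sim.get("blast_fractions") is not None:
                sim["blast_fractions"] = np.asarray(sim["blast_fractions"], dtype=float)
            if sim.get("mutation_genes") is not None:
                sim["mutation_genes"] = {
                    k: tuple(v) for k, v in sim["mutation_genes"].items()
                }
            raw["sim"] = SimulationConfig(**sim)
        if raw.get("plan"):
            raw["plan"] = NestedSplitPlan(**raw["plan"])
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage on a simulated cohort; return the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
    }
    (out / "config.json").write_text(config.to_json())

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"name": stage, **info})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    # --- synthetic cohort ---------------------------------------------------
    sim = dataclasses.replace(config.sim, seed=seeds["simulate"])
    counts, meta = simulate_counts(sim)
    truth_sig = meta.attrs["signature_genes"]
    write_expression_tsv(counts, out / "counts.tsv")
    write_metadata_tsv(meta, out / "metadata.tsv")
    done("simulate", n_samples=counts.n_samples, n_genes=counts.n_genes)

    # --- preprocessing ------------------------------------------------------
    normalized = normalize_library_size(counts)
    transformed = vst(normalized, prior_count=config.vst_prior_count)
    write_expression_tsv(transformed, out / "vst.tsv")
    done("normalize")
    done("vst", prior_count=config.vst_prior_count)

    # --- blast correction ---------------------------------------------------
    if config.do_blast_correction:
        bc = correct_for_blasts(transformed, meta["blast_pct"].to_numpy())
        corrected = bc.corrected
        bc.report().to_csv(out / "pc_report.tsv", sep="\t", index=False)
        done("blast_correction", removed_pcs=bc.removed_pcs)
    else:
        corrected = transformed.with_values(transformed.values, "blast_corrected")
        done("blast_correction", skipped=True)
    write_expression_tsv(corrected, out / "corrected.tsv")

    # --- gene-set scores and consensus labels -------------------------------
    sets = simulate_gene_sets(
        sim, list(counts.gene_ids), truth_sig, meta.attrs["signature_signs"]
    )
    write_gmt(sets, out / "gene_sets.gmt")
    scores = gene_set_scores(corrected, sets)
    scores.to_csv(out / "set_scores.tsv", sep="\t")
    top = top_variable(scores, min(config.n_top_scores, scores.shape[0]))
    done("gene_set_scores", n_sets=scores.shape[0], n_top=top.shape[0])

    consensus = consensus_cluster(
        top,
        k=config.k,
        n_resamples=config.consensus_resamples,
        subsample_fraction=config.subsample_fraction,
        seed=seeds["consensus_clustering"],
    )
    labels, mapping = reassign_labels(consensus, meta["raw_label"])
    consensus.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t")
    mapping.to_csv(out / "labels.tsv", sep="\t", index_label="sample_id")
    done("consensus_clustering", n_responders=int((labels == RESPONDER_CLASS).sum()))

    # --- differential enrichment -> feature pool ----------------------------
    y = (labels == RESPONDER_CLASS).astype(int)
    ranked = moderated_t(corrected, y)
    ranked.to_csv(out / "ranked_genes.tsv", sep="\t", index_label="gene_id")
    gsea = preranked_gsea(
        ranked, sets, n_permutations=config.gsea_permutations,
        seed=seeds["differential_enrichment"],
    )
    gsea.table.to_csv(out / "gsea.tsv", sep="\t")
    done("differential_enrichment", n_sets=len(gsea.table))

    pool = build_feature_pool(gsea, ranked, alpha=config.alpha)
    (out / "feature_pool.txt").write_text("\n".join(pool) + "\n")
    done("feature_pool", n_genes=len(pool))

    # --- nested boosted signature -------------------------------------------
    plan = dataclasses.replace(config.plan, seed=seeds["signature_ensemble"])
    blommed = blom(corrected)
    x_pool = blommed.values.loc[pool].T
    splits = make_split_plan(y, plan)
    (out / "splits.json").write_text(splits.to_json())

    gain1 = feature_selection_round(
        x_pool, y, splits, reps=plan.round1_reps,
        val_fraction=plan.round1_val_fraction, seed=plan.seed,
    )
    top50 = list(gain1.index[: min(plan.top_k_round1, len(gain1))])
    gain2 = feature_selection_round(
        x_pool[top50], y, splits, reps=plan.round1_reps,
        val_fraction=plan.round1_val_fraction, seed=plan.seed + 1,
    )
    top10 = list(gain2.index[: min(plan.top_k_round2, len(gain2))])
    tuned = tune_hyperparameters(
        x_pool[top10], y, grid=config.tuning_grid,
        cv_folds=plan.cv_folds, cv_repeats=plan.cv_repeats, seed=plan.seed + 2,
    )
    ensemble = fit_final_ensemble(x_pool[top10], y, splits, tuned, plan)
    ensemble.save(out / "ensemble")
    gain2.rename("mean_gain").to_csv(out / "round2_gain.tsv", sep="\t", index_label="gene_id")
    done("signature_ensemble", selected_genes=top10, n_models=len(ensemble.models))

    prediction = predict(ensemble, blommed)
    prediction.to_frame().to_csv(out / "predictions.tsv", sep="\t", index_label="sample_id")
    done("predict", n_responders=int((prediction.calls == "responder").sum()))

    # --- mutation association ------------------------------------------------
    if config.do_mutation_association:
        mut = simulate_mutations(
            dataclasses.replace(sim, seed=seeds["mutation_association"]),
            prediction.modes,
        )
        write_mutations_long(mut, out / "mutations.tsv")
        filtered = filter_by_frequency(mut, config.min_mutation_count)
        if filtered.shape[1] == 0:
            warnings.warn("no gene passed the mutation frequency filter; association skipped")
            done("mutation_association", skipped=True)
        else:
            genes_en = select_by_elastic_net(
                prediction.modes, filtered, mixing=config.elastic_net_mixing,
                seed=seeds["mutation_association"],
            )
            genes_xgb = select_by_boosting(
                prediction.modes, filtered, seed=seeds["mutation_association"]
            )
            selected_union = list(dict.fromkeys([*genes_en.index, *genes_xgb.index]))
            if selected_union and len(filtered) > len(selected_union) + 1:
                summary = summarize_ols(
                    prediction.modes, filtered, list(genes_en.index), list(genes_xgb.index)
                )
                summary.table.to_csv(out / "mutation_association.tsv", sep="\t", index=False)
                done("mutation_association", n_selected=summary.n_selected)
            else:
                done("mutation_association", n_selected=0)
            spliceo = [g for g in ("SRSF2", "SF3B1", "U2AF1", "ZRSR2") if g in mut.columns]
            if spliceo:
                flag = mut[spliceo].any(axis=1).astype(int)
                calls = (prediction.calls == "responder").astype(int)
                try:
                    gt = group_test(calls, flag)
                    (out / "group_test.json").write_text(
                        json.dumps(
                            {
                                "statistic": gt.statistic,
                                "statistic_corrected": gt.statistic_corrected,
                                "p_value": gt.p_value,
                                "p_value_corrected": gt.p_value_corrected,
                                "df": gt.df,
                            },
                            indent=1,
                        )
                    )
                except ValueError as exc:
                    warnings.warn(f"group test skipped: {exc}")
    else:
        done("mutation_association", skipped=True)

    # --- exact clinical statistics -------------------------------------------
    stats_rows = []
    meta_stats = meta.copy()
    meta_stats["response"] = meta_stats["raw_label"].map(
        lambda lab: "CR" if lab == "BMR" else None
    )
    meta_stats["bmr"] = meta_stats["raw_label"] == "BMR"
    mut_cols = [c for c in meta_stats.columns if c.startswith("mut_")]
    for strat in mut_cols:
        try:
            table = tabulate_responses(meta_stats, "bmr", strat)
            res = cmle_odds_ratio(table)
            stats_rows.append(
                {
                    "stratifier": strat,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "cmle_or": res.cmle_or,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_value": res.p_two_sided,
                }
            )
        except ValueError as exc:
            warnings.warn(f"clinical stats for {strat} skipped: {exc}")
    pd.DataFrame(stats_rows).to_csv(out / "clinical_stats.tsv", sep="\t", index=False)
    done("clinical_stats", n_tables=len(stats_rows))
    return out
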