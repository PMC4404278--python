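"""End-to-end orchestration: simulate -> normalize -> test -> cluster -> enrich.

Two entry points mirror the two experiments: :func:`run_gf_vs_cr` performs
the per-fraction GF-vs-CR moderated-t contrasts, the Venn specificity
partition, sample dendrogram and enrichment screens; :func:`run_colonization`
gates time-varying genes per fraction with one-way ANOVA and consensus-
clusters them into trajectory archetypes.  Both write their outputs under a
run directory together with a machine-readable manifest (configuration hash,
seed, package version), and both are byte-deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, GroundTruth, StudyDesign, ValidationError
from . import clustering, diffexp, enrichment, io, normalize, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_gf_vs_cr", "run_colonization", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds and inputs for one end-to-end run.

    Exactly one of (matrix_path + metadata_path) or the simulation block is
    used; defaults carry the analysis cutoffs: differential expression at
    adjusted p < 0.001, GO-style terms at adjusted p < 1e-5 with more than
    5 overlap members, the 50 most significant regulators per fraction and
    1,000 background draws.
    """

    out_dir: str = "results"
    seed: int = 0
    matrix_path: str | None = None
    metadata_path: str | None = None
    # simulation block
    simulate: bool = True
    n_genes: int = 20000
    replicates_per_group: int = 5
    fraction_specific_rate: float = 0.086
    shared_rate: float = 0.014
    effect_size_mean: float = 2.0
    noise_sd: float = 0.35
    timecourse_noise_sd: float = 0.1
    # thresholds
    de_alpha: float = 0.001
    go_p_ceiling: float = 1e-5
    min_members: int = 5
    top_k: int = 50
    background_draws: int = 1000
    # clustering
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 250
    subsample_fraction: float = 0.8
    anova_alpha: float = 0.001
    # enrichment inputs (optional, simulated when absent and simulate=True)
    gene_sets_path: str | None = None
    n_terms: int = 60
    enrichment_strength: float = 0.8

    def validate(self) -> None:
        if not (0 < self.de_alpha < 1) or not (0 < self.go_p_ceiling < 1):
            raise ValidationError("alpha thresholds must be in (0, 1)")
        has_paths = self.matrix_path is not None and self.metadata_path is not None
        if has_paths == self.simulate:
            raise ValidationError(
                "config must use exactly one of input paths or the simulation block"
            )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _write_manifest(config: PipelineConfig, out: Path, stage: str) -> None:
    io.write_json(
        {
            "stage": stage,
            "config": asdict(config),
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
        out / "manifest.json",
    )


def _load_inputs(config: PipelineConfig, conditions, replicates) -> tuple:
    """Return (matrix, annotation, design-or-None, truth-or-None)."""
    if config.simulate:
        design = simulate.generate_design(
            ("ileum", "colon"), ("tip", "crypt"), conditions, replicates,
            seed=config.seed,
        )
        return design, None
    raise NotImplementedError


def run_gf_vs_cr(config: PipelineConfig) -> dict:
    """GF-vs-CR experiment: contrasts, Venn partition, enrichment screens."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.simulate:
        design = simulate.generate_design(
            ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"),
            config.replicates_per_group, seed=config.seed,
        )
        matrix, truth = simulate.simulate_expression(
            design,
            n_genes=config.n_genes,
            fraction_specific_rate=config.fraction_specific_rate,
            shared_rate=config.shared_rate,
            effect_size_mean=config.effect_size_mean,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        annotation = design.annotation()
        io.write_json(truth.to_jsonable(), out / "ground_truth.json")
    else:
        matrix = io.read_expression_tsv(config.matrix_path)
        annotation = io.read_annotation_tsv(config.metadata_path)
    annotation.check_matches(matrix)
    logger.info("stage normalize: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    matrix = normalize.quantile_normalize(normalize.log2_if_needed(matrix))
    io.write_expression_tsv(matrix, out / "expression_normalized.tsv")
    io.write_annotation_tsv(annotation, out / "metadata.tsv")

    # sample dendrogram on Pearson distance
    dist = clustering.pearson_distance(matrix.values.T, labels=matrix.sample_ids)
    dendro = clustering.hierarchical_cluster(dist, matrix.sample_ids)
    io.write_newick(dendro.linkage_matrix, dendro.labels, out / "samples_dendrogram.nwk")

    combos = [(t, f) for t in ("ileum", "colon") for f in ("tip", "crypt")]
    combos = [c for c in combos
              if annotation.samples_where(tissue=c[0], fraction=c[1])]
    contrasts = {}
    for tissue, fraction in combos:
        contrast = diffexp.moderated_t_contrast(
            matrix, annotation,
            dict(tissue=tissue, fraction=fraction, condition="CR"),
            dict(tissue=tissue, fraction=fraction, condition="GF"),
        )
        contrasts[(tissue, fraction)] = contrast
        tab = contrast.table.copy()
        tab["significant"] = tab["p_adj"] < config.de_alpha
        tab.to_csv(out / f"diffexp_{tissue}_{fraction}.tsv", sep="\t")
        logger.info(
            "stage diffexp %s/%s: %d of %d genes significant at adj p<%g",
            tissue, fraction, int(tab["significant"].sum()), len(tab), config.de_alpha,
        )

    partition = diffexp.significant_sets(contrasts, alpha=config.de_alpha)
    summary = diffexp.specificity_summary(partition)
    venn = {
        "alpha": config.de_alpha,
        "exclusive_counts": {
            "_".join(k): v for k, v in partition.exclusive_counts().items()
        },
        "region_counts": {
            "+".join(sorted("_".join(k) for k in key)): count
            for key, count in partition.region_counts().items()
        },
        "union": len(partition.union()),
        "n_specific": summary.n_specific,
        "percent_specific": summary.percent_specific,
    }
    io.write_json(venn, out / "venn_partition.json")

    universe = set(matrix.gene_ids)
    if config.gene_sets_path:
        collection = io.read_gmt(config.gene_sets_path)
    elif truth is not None:
        collection = simulate.generate_gene_sets(
            universe, truth, n_terms=config.n_terms,
            term_size_range=(6, max(20, config.n_genes // 100)),
            enrichment_strength=config.enrichment_strength, seed=config.seed,
        )
        io.write_gmt(collection, out / "gene_sets.gmt")
    else:
        collection = {}

    enrich_results = {}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(9,)))
    for combo in combos:
        gene_list = partition.sets[combo]
        if not gene_list or not collection:
            continue
        res = enrichment.gene_set_enrichment(
            gene_list, collection, universe,
            min_members=config.min_members, p_ceiling=config.go_p_ceiling,
        )
        res.to_csv(out / f"enrichment_{combo[0]}_{combo[1]}.tsv", sep="\t")
        enrich_results[combo] = res
        # direction-labeled screens: up- and down-regulated lists separately
        diffs = contrasts[combo].table["mean_diff"]
        for direction, sub_list in (
            ("up", {g for g in gene_list if diffs[g] > 0}),
            ("down", {g for g in gene_list if diffs[g] < 0}),
        ):
            if not sub_list:
                continue
            res_dir = enrichment.gene_set_enrichment(
                sub_list, collection, universe,
                min_members=config.min_members, p_ceiling=config.go_p_ceiling,
            )
            res_dir.insert(0, "direction", direction)
            res_dir.to_csv(
                out / f"enrichment_{combo[0]}_{combo[1]}_{direction}.tsv", sep="\t"
            )

    result = {
        "matrix": matrix,
        "annotation": annotation,
        "contrasts": contrasts,
        "partition": partition,
        "specificity": summary,
        "dendrogram": dendro,
        "gene_sets": collection,
        "enrichment": enrich_results,
        "ground_truth": truth,
    }
    if truth is not None:
        result["recovery"] = _recovery_report(partition, truth, out)
    _write_manifest(config, out, "gf_vs_cr")
    return result


def _recovery_report(partition, truth: GroundTruth, out: Path) -> dict:
    """Compare the Venn partition with the planted truth."""
    exclusive = partition.exclusive_sets()
    per_fraction = {}
    n_correct = 0
    n_planted = 0
    for combo, genes in truth.regulated_genes.items():
        if not isinstance(combo, tuple):
            continue
        planted = set(genes)
        correct = len(planted & exclusive.get(combo, set()))
        per_fraction["_".join(combo)] = {
            "planted": len(planted),
            "in_correct_exclusive_region": correct,
        }
        n_correct += correct
        n_planted += len(planted)
    shared = set(truth.regulated_genes.get("shared", {}))
    central = partition.regions().get(frozenset(partition.labels), set())
    report = {
        "per_fraction": per_fraction,
        "n_planted_specific": n_planted,
        "n_in_correct_exclusive_region": n_correct,
        "percent_recovered_specific": (
            100.0 * n_correct / n_planted if n_planted else None
        ),
        "shared_planted": len(shared),
        "shared_in_central_region": len(shared & central),
    }
    io.write_json(report, out / "recovery_report.json")
    return report


def run_colonization(config: PipelineConfig) -> dict:
    """Colonization time course: ANOVA gate + consensus clustering per fraction."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        raise NotImplementedError(
            "colonization runs currently require the simulation block"
        )
    days = ("0", "1", "3", "5", "7")
    design = simulate.generate_design(
        ("ileum", "colon"), ("tip", "crypt"), days,
        min(config.replicates_per_group, 3), seed=config.seed,
    )
    gfcr_design = simulate.generate_design(
        ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"),
        config.replicates_per_group, seed=config.seed,
    )
    _, truth = simulate.simulate_expression(
        gfcr_design,
        n_genes=config.n_genes,
        fraction_specific_rate=config.fraction_specific_rate,
        shared_rate=config.shared_rate,
        effect_size_mean=config.effect_size_mean,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    genes = simulate._gene_ids(config.n_genes)
    matrix = simulate.simulate_timecourse(
        design, truth, genes, noise_sd=config.timecourse_noise_sd, seed=config.seed,
    )
    annotation = design.annotation()
    io.write_json(truth.to_jsonable(), out / "ground_truth.json")
    io.write_expression_tsv(matrix, out / "timecourse_expression.tsv")
    io.write_annotation_tsv(annotation, out / "timecourse_metadata.tsv")

    dist = clustering.pearson_distance(matrix.values.T, labels=matrix.sample_ids)
    dendro = clustering.hierarchical_cluster(dist, matrix.sample_ids)
    io.write_newick(dendro.linkage_matrix, dendro.labels, out / "samples_dendrogram.nwk")

    results = {}
    for tissue in design.tissues:
        for fraction in design.fractions:
            samples = annotation.samples_where(tissue=tissue, fraction=fraction)
            sub_matrix = matrix.subset_samples(samples)
            sub_annotation = type(annotation)(annotation.table.loc[samples])
            gate = clustering.anova_gate(sub_matrix, sub_annotation,
                                         alpha=config.anova_alpha)
            gated = sorted(gate.gated)
            logger.info(
                "stage anova_gate %s/%s: %d of %d genes pass adj p<%g",
                tissue, fraction, len(gated), matrix.n_genes, config.anova_alpha,
            )
            if len(gated) < config.k_max * 5:
                logger.warning(
                    "%s/%s: too few gated genes (%d) for consensus clustering",
                    tissue, fraction, len(gated),
                )
                continue
            profiles = clustering.day_profiles(sub_matrix, sub_annotation,
                                               genes=gated, standardize=True)
            consensus = clustering.consensus_cluster(
                profiles,
                k_range=range(config.k_min, config.k_max + 1),
                n_resamples=config.n_resamples,
                subsample_fraction=config.subsample_fraction,
                seed=config.seed,
            )
            consensus.profiles = clustering.cluster_profiles(
                consensus.assignment, sub_matrix, sub_annotation
            )
            key = f"{tissue}_{fraction}"
            pd.DataFrame(
                {"gene": list(consensus.assignment),
                 "cluster": list(consensus.assignment.values())}
            ).to_csv(out / f"clusters_{key}.tsv", sep="\t", index=False)
            consensus.profiles.to_csv(out / f"cluster_profiles_{key}.tsv",
                                      sep="\t", index=False)
            pd.DataFrame(
                consensus.consensus[consensus.k_star],
                index=consensus.gene_ids, columns=consensus.gene_ids,
            ).to_csv(out / f"consensus_matrix_{key}.tsv", sep="\t")
            results[(tissue, fraction)] = {"gate": gate, "consensus": consensus}

    chosen = {"_".join(k): v["consensus"].chosen_k for k, v in results.items()}
    io.write_json({"chosen_k": chosen}, out / "chosen_k.json")
    _write_manifest(config, out, "colonization")
    return {
        "matrix": matrix,
        "annotation": annotation,
        "dendrogram": dendro,
        "fractions": results,
        "ground_truth": truth,
        "chosen_k": chosen,
    }
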