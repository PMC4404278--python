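"""Synthetic data with the statistical structure the analysis assumes.

The generators emulate the two study designs — a germ-free versus
conventionally-raised (GF/CR) comparison over 2 tissues x 2 epithelial
fractions x 5 replicates (40 arrays) and a colonization time course over
days 0/1/3/5/7 with 3 replicates (60 arrays) — with known planted truth:
which genes are microbially regulated in which fraction, which time-course
archetype each follows, which gene-set terms are truly enriched and which
promoters carry a planted motif site.  All generators are deterministic
given their arguments and seed; a single pipeline seed fans out to
independent child streams via spawn keys so modules are reproducible in
isolation.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GroundTruth,
    StudyDesign,
    ValidationError,
)
from .motifs import MotifMatrix, reverse_complement

__all__ = [
    "generate_design",
    "simulate_expression",
    "simulate_timecourse",
    "default_archetype_shapes",
    "generate_gene_sets",
    "generate_promoters",
    "simulate_qpcr",
    "child_rng",
]

# Baseline log2 intensity distribution: typical microarray dynamic range.
BASELINE_MEAN = 7.0
BASELINE_SD = 2.0
# Effect magnitudes: Gamma with this shape around the requested mean, random
# sign.  A high shape concentrates effects near the mean so planted genes
# are individually detectable at the study's replicate numbers.
EFFECT_GAMMA_SHAPE = 16.0
# Archetype amplitudes (log2 units): strong up/down for archetypes 1/2,
# mild up/down for archetypes 3/4.
STRONG_STEP = 2.0
MILD_STEP = 0.75
# Per-array residual sd (log2) of the time-course arrays.  Mild-archetype
# genes must clear the ANOVA gate at adjusted p<0.001 with 3 replicates per
# day, which bounds the realistic noise level from above.
TIMECOURSE_NOISE_SD = 0.1


def child_rng(seed: int, *key) -> np.random.Generator:
    """Independent child stream of a pipeline seed, keyed by purpose.

    Keys are digested with a process-independent hash so streams are
    bit-identical across runs and interpreters.
    """
    spawn = tuple(
        k if isinstance(k, int)
        else int.from_bytes(hashlib.sha256(str(k).encode()).digest()[:4], "big")
        for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


def generate_design(
    tissues, fractions, conditions, replicates_per_group: int, seed: int = 0
) -> StudyDesign:
    """Fully crossed design over tissues x fractions x conditions.

    The GF/CR design (2 x 2 x 2 x 5) yields 40 samples; the colonization
    design (2 x 2 x 5 days x 3) yields 60.
    """
    tissues = tuple(tissues)
    fractions = tuple(fractions)
    conditions = tuple(conditions)
    for name, labels in (("tissues", tissues), ("fractions", fractions),
                         ("conditions", conditions)):
        if not labels:
            raise ValidationError(f"{name} must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate labels within {name}: {labels}")
    if replicates_per_group < 2:
        raise ValidationError("replicates_per_group must be >= 2")
    return StudyDesign(
        tissues=tissues,
        fractions=fractions,
        conditions=conditions,
        replicates_per_group=int(replicates_per_group),
        seed=int(seed),
    )


def _gene_ids(n_genes: int) -> list:
    width = len(str(n_genes))
    return [f"g{str(i).zfill(width)}" for i in range(1, n_genes + 1)]


def simulate_expression(
    design: StudyDesign,
    n_genes: int = 20000,
    fraction_specific_rate: float = 0.086,
    shared_rate: float = 0.014,
    effect_size_mean: float = 2.0,
    noise_sd: float = 0.35,
    seed: int = 0,
    effect_shape: float = EFFECT_GAMMA_SHAPE,
    variance_prior_df: float | None = None,
    fraction_offset_sd: float = 2.0,
    tissue_offset_sd: float = 1.0,
) -> tuple:
    """Simulate the GF/CR expression matrix with planted regulated genes.

    Baselines are normal on the log2 scale (mean 7, sd 2).  A fraction of
    genes is regulated in exactly one (tissue, fraction) group, a further
    fraction in all groups ("shared"); regulated genes receive an additive
    status effect in their non-baseline (CR) samples, with per-gene log2
    magnitude drawn from a Gamma around ``effect_size_mean`` and random
    sign.  With the default rates (8.6% specific + 1.4% shared) about 10%
    of the transcriptome is regulated and 86% of regulated genes are
    fraction specific.  ``variance_prior_df`` optionally draws per-gene
    noise variances from a scaled inverse-chi-square around ``noise_sd**2``
    instead of the constant-variance default.

    Per-gene baseline signatures distinguish the fraction levels
    (sd ``fraction_offset_sd``) and tissue levels (sd ``tissue_offset_sd``);
    with the defaults these dominate the status effects, so sample-level
    clustering separates fraction first, then tissue, then bacterial
    status.

    Returns ``(ExpressionMatrix, GroundTruth)``.
    """
    if n_genes < 100:
        raise ValidationError("n_genes must be >= 100")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    if fraction_specific_rate < 0 or shared_rate < 0:
        raise ValidationError("rates must be non-negative")
    if fraction_specific_rate + shared_rate > 1:
        raise ValidationError("rates must sum to at most 1")

    annotation = design.annotation()
    samples = annotation.sample_ids
    genes = _gene_ids(n_genes)
    baseline_cond = design.conditions[0]

    rng = child_rng(seed, "expression")
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)

    combos = [(t, f) for t in design.tissues for f in design.fractions]
    n_specific = int(round(fraction_specific_rate * n_genes))
    n_shared = int(round(shared_rate * n_genes))
    chosen = rng.choice(n_genes, size=n_specific + n_shared, replace=False)
    specific_idx = chosen[:n_specific]
    shared_idx = chosen[n_specific:]

    def draw_effects(k: int) -> np.ndarray:
        if k == 0:
            return np.empty(0)
        if effect_size_mean == 0:
            return np.zeros(k)
        mags = rng.gamma(effect_shape, effect_size_mean / effect_shape, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        return mags * signs

    truth = GroundTruth()
    effect = np.zeros((n_genes, len(combos)))
    per_combo = np.array_split(specific_idx, len(combos))
    for c, (combo, idx) in enumerate(zip(combos, per_combo)):
        effs = draw_effects(len(idx))
        effect[idx, c] = effs
        truth.regulated_genes[combo] = {
            genes[i]: float(e) for i, e in zip(idx, effs)
        }
    shared_effs = draw_effects(len(shared_idx))
    effect[shared_idx, :] = shared_effs[:, None]
    truth.regulated_genes["shared"] = {
        genes[i]: float(e) for i, e in zip(shared_idx, shared_effs)
    }

    # archetype assignment for the time-course counterpart: every regulated
    # gene in a fraction follows one of 4 trajectory archetypes there
    for c, combo in enumerate(combos):
        assigned = {}
        members = list(truth.regulated_genes[combo]) + list(
            truth.regulated_genes["shared"]
        )
        archetypes = rng.integers(1, 5, size=len(members))
        for gene, a in zip(members, archetypes):
            assigned[gene] = int(a)
        truth.cluster_assignments[combo] = assigned

    if variance_prior_df is not None:
        # per-gene variances ~ noise_sd^2 * d0 / chi2_{d0}
        gene_var = noise_sd**2 * variance_prior_df / rng.chisquare(
            variance_prior_df, size=n_genes
        )
        gene_sd = np.sqrt(gene_var)
    else:
        gene_sd = np.full(n_genes, noise_sd)

    # per-gene baseline signatures of the non-reference tissue/fraction levels
    tissue_sig = {
        t: rng.normal(0.0, tissue_offset_sd, size=n_genes)
        for t in design.tissues[1:]
    }
    fraction_sig = {
        f: rng.normal(0.0, fraction_offset_sd, size=n_genes)
        for f in design.fractions[1:]
    }

    combo_index = {combo: c for c, combo in enumerate(combos)}
    values = np.empty((n_genes, len(samples)))
    for j, sid in enumerate(samples):
        row = annotation.table.loc[sid]
        mu = baseline.copy()
        if row["tissue"] in tissue_sig:
            mu = mu + tissue_sig[row["tissue"]]
        if row["fraction"] in fraction_sig:
            mu = mu + fraction_sig[row["fraction"]]
        if row["condition"] != baseline_cond:
            mu = mu + effect[:, combo_index[(row["tissue"], row["fraction"])]]
        values[:, j] = mu + rng.normal(0.0, 1.0, size=n_genes) * gene_sd

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        provenance=[f"simulate_expression(seed={seed})"],
    )
    return matrix, truth


def default_archetype_shapes(days, step_after_day) -> dict:
    """Default archetype trajectories over the sampled days.

    Archetype 1: strong step up after ``step_after_day``; 2: strong step
    down; 3: mild gradual increase over the whole period; 4: mild gradual
    decrease.  Ileum-like kinetics use a step between days 3 and 5
    (``step_after_day=3``); colon-like between days 1 and 3
    (``step_after_day=1``).  The mild archetypes are ramps rather than
    scaled-down steps: clustering works on z-scored profiles under Pearson
    distance, both of which are scale-invariant, so archetypes must differ
    in shape — not just amplitude — to be distinguishable.
    """
    days = np.asarray([float(str(d).lstrip("d")) for d in days])
    after = (days > step_after_day).astype(float)
    ramp = (days - days.min()) / (days.max() - days.min())
    return {
        1: STRONG_STEP * after,
        2: -STRONG_STEP * after,
        3: MILD_STEP * ramp,
        4: -MILD_STEP * ramp,
    }


def simulate_timecourse(
    design: StudyDesign,
    ground_truth: GroundTruth,
    gene_ids,
    archetype_shapes: dict | None = None,
    noise_sd: float = TIMECOURSE_NOISE_SD,
    seed: int = 0,
    fraction_offset_sd: float = 2.0,
    tissue_offset_sd: float = 1.0,
) -> ExpressionMatrix:
    """Simulate the colonization time course from planted archetypes.

    ``archetype_shapes`` maps tissue -> {archetype id: trajectory over the
    design's days}; by default the colon steps between days 1 and 3 and the
    ileum between days 3 and 5, matching the faster colonic response.
    Genes with an archetype assignment in a (tissue, fraction) follow that
    trajectory around their baseline; all other genes are flat.
    """
    if not design.is_timecourse:
        raise ValidationError("design conditions must be day labels")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    days = design.conditions
    if archetype_shapes is None:
        archetype_shapes = {}
        for tissue in design.tissues:
            step_after = 1 if "colon" in str(tissue).lower() else 3
            archetype_shapes[tissue] = default_archetype_shapes(days, step_after)
    for tissue in design.tissues:
        if tissue not in archetype_shapes:
            raise ValidationError(f"missing archetype shapes for tissue {tissue!r}")
        for a in (1, 2, 3, 4):
            if a not in archetype_shapes[tissue]:
                raise ValidationError(f"missing shape for archetype {a} ({tissue})")
            if len(archetype_shapes[tissue][a]) != len(days):
                raise ValidationError(
                    f"shape for archetype {a} ({tissue}) must cover {len(days)} days"
                )

    genes = list(gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    annotation = design.annotation()
    samples = annotation.sample_ids
    day_index = {d: i for i, d in enumerate(days)}

    rng = child_rng(seed, "timecourse")
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    tissue_sig = {
        t: rng.normal(0.0, tissue_offset_sd, size=n_genes)
        for t in design.tissues[1:]
    }
    fraction_sig = {
        f: rng.normal(0.0, fraction_offset_sd, size=n_genes)
        for f in design.fractions[1:]
    }

    # per-(tissue, fraction) archetype offsets
    offsets = {}
    for combo, assigned in ground_truth.cluster_assignments.items():
        if not isinstance(combo, tuple):
            continue
        tissue = combo[0]
        block = np.zeros((n_genes, len(days)))
        for gene, archetype in assigned.items():
            if gene in gene_pos:
                block[gene_pos[gene]] = np.asarray(
                    archetype_shapes[tissue][archetype], dtype=float
                )
        offsets[combo] = block

    values = np.empty((n_genes, len(samples)))
    for j, sid in enumerate(samples):
        row = annotation.table.loc[sid]
        combo = (row["tissue"], row["fraction"])
        mu = baseline.copy()
        if row["tissue"] in tissue_sig:
            mu = mu + tissue_sig[row["tissue"]]
        if row["fraction"] in fraction_sig:
            mu = mu + fraction_sig[row["fraction"]]
        if combo in offsets:
            mu = mu + offsets[combo][:, day_index[row["condition"]]]
        noise = rng.normal(0.0, 1.0, size=n_genes) * noise_sd if noise_sd > 0 else 0.0
        values[:, j] = mu + noise

    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        provenance=[f"simulate_timecourse(seed={seed})"],
    )


def generate_gene_sets(
    universe,
    ground_truth: GroundTruth,
    n_terms: int = 100,
    term_size_range: tuple = (6, 200),
    enrichment_strength: float = 0.8,
    n_enriched_per_fraction: int = 3,
    seed: int = 0,
) -> dict:
    """Generate a GMT-serializable gene-set collection with planted truth.

    For each (tissue, fraction) with regulated genes, ``n_enriched_per_
    fraction`` terms are over-sampled from that fraction's regulated genes:
    a proportion ``enrichment_strength`` of each such term's members comes
    from the regulated set (all of them at strength 1).  Remaining terms
    are uniform draws from the universe.  Truly enriched term ids are
    recorded in ``ground_truth.enriched_terms``.
    """
    if n_terms <= 0:
        raise ValidationError("n_terms must be positive")
    universe = sorted(set(universe))
    lo, hi = term_size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ValidationError(f"term_size_range {term_size_range} outside universe")
    if not (0 <= enrichment_strength <= 1):
        raise ValidationError("enrichment_strength must be in [0, 1]")
    rng = child_rng(seed, "gene_sets")
    universe_arr = np.array(universe)

    collection: dict = {}
    combos = [k for k in ground_truth.regulated_genes if isinstance(k, tuple)]
    term_no = 0
    for combo in combos:
        regulated = sorted(ground_truth.regulated_in(*combo))
        if not regulated:
            continue
        key = "_".join(combo)
        ground_truth.enriched_terms.setdefault(combo, set())
        for _ in range(n_enriched_per_fraction):
            term_no += 1
            term = f"TERM{term_no:04d}_{key}"
            size = int(rng.integers(lo, hi + 1))
            n_reg = min(int(round(enrichment_strength * size)), len(regulated))
            members = set(rng.choice(regulated, size=n_reg, replace=False))
            pool = np.array([g for g in universe if g not in members])
            n_fill = min(size - len(members), len(pool))
            if n_fill > 0:
                if enrichment_strength >= 1.0:
                    # maximal enrichment keeps the term inside the regulated set
                    reg_pool = np.array([g for g in regulated if g not in members])
                    fill = rng.choice(reg_pool, size=min(n_fill, len(reg_pool)),
                                      replace=False)
                else:
                    fill = rng.choice(pool, size=n_fill, replace=False)
                members |= set(fill)
            collection[term] = (f"planted enriched in {key}", members)
            ground_truth.enriched_terms[combo].add(term)
    while term_no < n_terms:
        term_no += 1
        term = f"TERM{term_no:04d}_null"
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(universe_arr, size=size, replace=False))
        collection[term] = ("background term", members)
    return collection


def generate_promoters(
    universe,
    motif_matrices,
    planting_plan: dict,
    promoter_length: int = 1000,
    background_base_freqs=None,
    seed: int = 0,
) -> tuple:
    """Generate promoter sequences with planted motif consensus sites.

    Background sequence is i.i.d. from ``background_base_freqs`` (uniform
    A/C/G/T by default).  For each motif in ``planting_plan`` (motif id ->
    gene ids) the motif's consensus is written at a random position and
    strand, recorded in the returned planted-targets map
    ``{motif id: {gene: (start, strand)}}``.

    Returns ``(promoters, planted_motif_targets)``.
    """
    motif_by_id = {m.id: m for m in motif_matrices}
    if background_base_freqs is None:
        background_base_freqs = np.full(4, 0.25)
    q = np.asarray(background_base_freqs, dtype=float)
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValidationError("background base frequencies must sum to 1")
    for motif in motif_matrices:
        if len(motif) > promoter_length:
            raise ValidationError(
                f"motif {motif.id} (length {len(motif)}) longer than promoter"
            )
    for motif_id, genes in planting_plan.items():
        if motif_id not in motif_by_id:
            raise ValidationError(f"planting plan references unknown motif {motif_id!r}")
        unknown = set(genes) - set(universe)
        if unknown:
            raise ValidationError(f"planting plan genes outside universe: {sorted(unknown)[:5]}")

    rng = child_rng(seed, "promoters")
    bases = np.array(list("ACGT"))
    promoters: dict = {}
    for gene in sorted(set(universe)):
        seq = "".join(rng.choice(bases, size=promoter_length, p=q))
        promoters[gene] = seq

    planted: dict = {}
    for motif_id in sorted(planting_plan):
        motif = motif_by_id[motif_id]
        site = motif.consensus()
        planted[motif_id] = {}
        for gene in sorted(set(planting_plan[motif_id])):
            start = int(rng.integers(0, promoter_length - len(site) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = site if strand == "+" else reverse_complement(site)
            seq = promoters[gene]
            promoters[gene] = seq[:start] + insert + seq[start + len(site):]
            planted[motif_id][gene] = (start, strand)
    return promoters, planted


def simulate_qpcr(
    design: StudyDesign,
    regulated_fold_changes: dict,
    ct_ref_mean: float = 20.0,
    noise_sd: float = 0.2,
    target_offset: float = 5.0,
    reference_gene: str = "L32",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct plate for the GF/CR design.

    ``regulated_fold_changes`` maps target gene -> fold change (CR vs GF),
    either a scalar applied in every tissue/fraction or a mapping
    ``{(tissue, fraction): fold}``.  Per sample, the reference gene gets
    Ct ~ Normal(ct_ref_mean, noise_sd) and each target
    ``Ct = Ct_ref + target_offset - log2(level) + noise``, so a true fold
    change f yields expected delta-delta-Ct of -log2(f).
    """
    for gene, fc in regulated_fold_changes.items():
        folds = fc.values() if isinstance(fc, dict) else [fc]
        for f in folds:
            if not f > 0:
                raise ValidationError(f"fold change for {gene!r} must be > 0, got {f}")
    annotation = design.annotation()
    baseline_cond = design.conditions[0]
    rng = child_rng(seed, "qpcr")
    rows = []
    for sid in annotation.sample_ids:
        meta = annotation.table.loc[sid]
        ct_ref = ct_ref_mean + rng.normal(0.0, noise_sd) if noise_sd > 0 else ct_ref_mean
        rows.append((reference_gene, sid, meta["tissue"], meta["fraction"],
                     meta["condition"], ct_ref))
        for gene in sorted(regulated_fold_changes):
            fc = regulated_fold_changes[gene]
            if isinstance(fc, dict):
                fold = fc.get((meta["tissue"], meta["fraction"]), 1.0)
            else:
                fold = fc
            level = fold if meta["condition"] != baseline_cond else 1.0
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            ct = ct_ref + target_offset - math.log2(level) + noise
            rows.append((gene, sid, meta["tissue"], meta["fraction"],
                         meta["condition"], ct))
    return pd.DataFrame(
        rows, columns=["gene", "sample", "tissue", "fraction", "status", "ct"]
    )
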