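"""Gene-set and regulator enrichment with an empirical resampling background.

Over-representation is tested with the one-sided Fisher / hypergeometric
upper tail.  For regulator (and miRNA) target maps, the observed Fisher p is
compared with an empirical background: the mean Fisher p over many random
gene lists of the same size drawn uniformly from the universe.  GO-style
collections are instead BH-adjusted across terms and filtered by a
significance ceiling and a minimum member count.  Per fraction, the top-k
most significant regulators are merged into a unique list whose
cross-fraction membership quantifies regulator specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diffexp import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "RegulatorTargets",
    "fisher_enrichment",
    "empirical_background",
    "regulator_enrichment",
    "gene_set_enrichment",
    "top_k_regulators",
    "regulator_specificity",
]


@dataclass
class EnrichmentRecord:
    """One term/regulator tested against one gene list.

    k = overlap, n = list size, K = term size in the universe, N = universe
    size.  ``background_p`` (regulator mode only) is the mean Fisher p over
    random same-size lists; ``enrichment_ratio = background_p / fisher_p``.
    """

    term: str
    k: int
    n: int
    K: int
    N: int
    fisher_p: float
    background_p: float | None = None
    p_adj: float | None = None
    passes_filter: bool = False

    @property
    def enrichment_ratio(self) -> float | None:
        if self.background_p is None:
            return None
        return self.background_p / self.fisher_p if self.fisher_p > 0 else np.inf


@dataclass
class RegulatorTargets:
    """Mapping regulator id -> set of target gene ids."""

    targets: dict
    provenance: str = "supplied_list"  # or "motif_scan"

    def restricted_to(self, universe: set) -> "RegulatorTargets":
        return RegulatorTargets(
            targets={r: set(t) & universe for r, t in self.targets.items()},
            provenance=self.provenance,
        )


def fisher_enrichment(gene_list, term_set, universe) -> EnrichmentRecord:
    """One-sided over-representation p for a gene list against one term.

    p = hypergeometric upper tail P(X >= k) with list size n, term size K
    and universe size N.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    term_set = set(term_set) & universe
    if not gene_list:
        raise ValidationError("gene list is empty")
    outside = gene_list - universe
    if outside:
        raise ValidationError(f"gene list not within universe: {sorted(outside)[:5]}")
    N = len(universe)
    n = len(gene_list)
    K = len(term_set)
    k = len(gene_list & term_set)
    # upper tail including k itself
    fisher_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fisher_p = min(max(fisher_p, np.nextafter(0, 1)), 1.0)
    return EnrichmentRecord(term="", k=k, n=n, K=K, N=N, fisher_p=fisher_p)


def empirical_background(
    list_size: int, term_set, universe, n_draws: int = 1000, seed: int = 0
) -> float:
    """Mean Fisher p of ``n_draws`` uniform random gene lists of ``list_size``.

    The random lists are drawn without replacement from the universe; the
    mean of their one-sided Fisher p-values against ``term_set`` serves as
    an empirical null reference for the observed enrichment.
    """
    universe = sorted(set(universe))
    N = len(universe)
    if list_size > N:
        raise ValidationError(f"list size {list_size} exceeds universe size {N}")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    term_set = set(term_set) & set(universe)
    K = len(term_set)
    term_mask = np.fromiter((g in term_set for g in universe), dtype=bool, count=N)
    rng = np.random.default_rng(seed)
    # p depends on the draw only through k; draw overlaps directly
    ks = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        idx = rng.choice(N, size=list_size, replace=False)
        ks[i] = int(term_mask[idx].sum())
    ps = stats.hypergeom.sf(ks - 1, N, K, list_size)
    return float(np.clip(ps, np.nextafter(0, 1), 1.0).mean())


def regulator_enrichment(
    gene_list,
    regulator_targets: RegulatorTargets,
    universe,
    n_draws: int = 1000,
    seed: int = 0,
    p_ceiling: float = 0.05,
) -> list:
    """Fisher + empirical-background enrichment for every regulator.

    Records are ranked by ascending Fisher p; a regulator is called
    enriched (``passes_filter``) when its Fisher p is below both the
    empirical background mean and ``p_ceiling``.  Regulators with empty
    target sets in the universe are skipped with a warning.
    """
    universe = set(universe)
    restricted = regulator_targets.restricted_to(universe)
    rng = np.random.default_rng(seed)
    records = []
    for regulator in sorted(restricted.targets):
        targets = restricted.targets[regulator]
        if not targets:
            logger.warning("regulator %s has no targets in the universe; skipped", regulator)
            continue
        rec = fisher_enrichment(gene_list, targets, universe)
        rec.term = regulator
        rec.background_p = empirical_background(
            rec.n, targets, universe, n_draws=n_draws,
            seed=int(rng.integers(2**31 - 1)),
        )
        rec.passes_filter = rec.fisher_p < rec.background_p and rec.fisher_p < p_ceiling
        records.append(rec)
    records.sort(key=lambda r: (r.fisher_p, -r.k, r.term))
    return records


def gene_set_enrichment(
    gene_list,
    collection: dict,
    universe,
    min_members: int = 5,
    p_ceiling: float = 1e-5,
) -> pd.DataFrame:
    """GO-style over-representation across a gene-set collection.

    Fisher/hypergeometric p per term, BH adjustment across terms, and a
    pass flag requiring adjusted p < ``p_ceiling`` AND overlap strictly
    greater than ``min_members`` genes (members counted within the
    universe).  Also reports -log10 adjusted p for heatmap export.
    """
    if min_members < 1:
        raise ValidationError("min_members must be >= 1")
    universe = set(universe)
    terms = sorted(collection)
    if not terms:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "fisher_p", "p_adj",
                     "neg_log10_p_adj", "passes_filter"]
        ).set_index("term")
    rows = []
    for term in terms:
        entry = collection[term]
        genes = entry[1] if isinstance(entry, tuple) else entry
        rec = fisher_enrichment(gene_list, genes, universe)
        rows.append((term, rec.k, rec.n, rec.K, rec.N, rec.fisher_p))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "fisher_p"]).set_index("term")
    df["p_adj"] = benjamini_hochberg(df["fisher_p"].to_numpy())
    df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    df["passes_filter"] = (df["p_adj"] < p_ceiling) & (df["k"] > min_members)
    return df


def top_k_regulators(records_per_fraction: dict, k: int = 50):
    """Top-k regulators per fraction plus the merged unique list.

    Ties on Fisher p break by larger overlap, then lexical id, so the
    selection is deterministic under record shuffling.  Fractions with
    fewer than k records return all of them with a warning.

    Returns ``(per_fraction_top, membership)`` where membership maps each
    unique regulator to the set of fraction labels in whose top list it
    appears.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    per_fraction: dict = {}
    membership: dict = {}
    for fraction, records in records_per_fraction.items():
        ordered = sorted(records, key=lambda r: (r.fisher_p, -r.k, r.term))
        if len(ordered) < k:
            logger.warning(
                "fraction %s has only %d regulators (< top %d); keeping all",
                fraction, len(ordered), k,
            )
        top = ordered[:k]
        per_fraction[fraction] = top
        for rec in top:
            membership.setdefault(rec.term, set()).add(fraction)
    return per_fraction, membership


@dataclass(frozen=True)
class RegulatorSpecificity:
    n_unique: int
    n_shared_all: int
    n_specific: int
    n_intermediate: int
    percent_shared: float | None
    percent_specific: float | None


def regulator_specificity(membership: dict, fractions=None) -> RegulatorSpecificity:
    """Cross-fraction specificity of the merged top-regulator list.

    shared = present in the top list of every analyzed fraction; specific =
    present in exactly one; percentages rounded to the nearest integer.
    """
    if not membership:
        return RegulatorSpecificity(0, 0, 0, 0, None, None)
    if fractions is None:
        fractions = set()
        for flags in membership.values():
            fractions |= set(flags)
    fractions = set(fractions)
    n_unique = len(membership)
    n_shared = sum(1 for flags in membership.values() if set(flags) == fractions)
    n_specific = sum(1 for flags in membership.values() if len(flags) == 1)
    return RegulatorSpecificity(
        n_unique=n_unique,
        n_shared_all=n_shared,
        n_specific=n_specific,
        n_intermediate=n_unique - n_shared - n_specific,
        percent_shared=round(100.0 * n_shared / n_unique),
        percent_specific=round(100.0 * n_specific / n_unique),
    )
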