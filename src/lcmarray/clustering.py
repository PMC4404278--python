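"""Sample-level hierarchical clustering and gene-level consensus clustering.

Samples are clustered hierarchically on Pearson correlation distance
(d = 1 - r) to check the expected separation of the study factors
(fraction, then tissue, then bacterial status).  For the colonization time
course, genes that vary over days (one-way ANOVA, BH-adjusted p below a
gate) are consensus-clustered: repeated gene subsampling, clustering of each
subsample, and accumulation of co-clustering frequencies into a consensus
matrix from which both the number of clusters K and the final assignment
are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError
from .diffexp import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "AnovaGate",
    "ConsensusResult",
    "pearson_distance",
    "hierarchical_cluster",
    "anova_gate",
    "day_profiles",
    "consensus_cluster",
    "cluster_profiles",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form plus leaf labels."""

    linkage_matrix: np.ndarray
    labels: list
    method: str = "average"

    def to_newick(self) -> str:
        from .io import linkage_to_newick

        return linkage_to_newick(self.linkage_matrix, self.labels)

    def cophenetic_distance(self, a, b) -> float:
        dist = cophenet(self.linkage_matrix)
        n = len(self.labels)
        ia, ib = self.labels.index(a), self.labels.index(b)
        if ia == ib:
            return 0.0
        i, j = min(ia, ib), max(ia, ib)
        # condensed index
        idx = n * i - i * (i + 1) // 2 + (j - i - 1)
        return float(dist[idx])

    def cut(self, k: int) -> dict:
        flat = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, flat)}


def pearson_distance(X: np.ndarray, labels=None) -> np.ndarray:
    """Pearson correlation distance d(i,j) = 1 - r(i,j) between rows of X.

    Symmetric with a zero diagonal and range [0, 2].  Rows with zero
    variance have no defined correlation and are rejected by name.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need >=2 profiles to compute distances")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        names = [labels[i] for i in bad[:5]] if labels is not None else bad[:5].tolist()
        raise ValidationError(f"constant profile(s), correlation undefined: {names}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d


def hierarchical_cluster(
    distance_matrix: np.ndarray, labels, method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix."""
    D = np.asarray(distance_matrix, dtype=float)
    if np.any(~np.isfinite(D)):
        raise ValidationError("distance matrix contains non-finite entries")
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method=method)
    return Dendrogram(linkage_matrix=Z, labels=list(labels), method=method)


@dataclass
class AnovaGate:
    """Per-gene one-way ANOVA across day groups and the gated gene set."""

    table: pd.DataFrame  # columns: F, p_raw, p_adj
    alpha: float

    @property
    def gated(self) -> set:
        return set(self.table.index[self.table["p_adj"] < self.alpha])


def anova_gate(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    alpha: float = 0.001,
    factor: str = "condition",
) -> AnovaGate:
    """Gate genes that vary over the colonization period.

    Classical one-way fixed-effects ANOVA per gene across the levels of
    ``factor`` (days), BH correction, gate at adjusted p < alpha.
    """
    annotation.check_matches(matrix)
    groups = annotation.groups(factor)
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >=2 groups")
    for level, samples in groups.items():
        if len(samples) < 2:
            raise ValidationError(f"group {level} has <2 replicates")

    blocks = [matrix.data[samples].to_numpy(dtype=float) for samples in groups.values()]
    n_total = sum(b.shape[1] for b in blocks)
    k = len(blocks)
    grand = np.hstack(blocks).mean(axis=1)
    ss_between = np.zeros(matrix.n_genes)
    ss_within = np.zeros(matrix.n_genes)
    for b in blocks:
        gm = b.mean(axis=1)
        ss_between += b.shape[1] * (gm - grand) ** 2
        ss_within += ((b - gm[:, None]) ** 2).sum(axis=1)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_within > 0, ms_between / np.where(ms_within > 0, ms_within, 1.0), np.inf)
    F = np.where((ms_within == 0) & (ms_between == 0), 0.0, F)
    p_raw = stats.f.sf(F, df_between, df_within)
    p_raw = np.where(np.isfinite(F), p_raw, 0.0)
    p_adj = benjamini_hochberg(p_raw)
    table = pd.DataFrame(
        {"F": F, "p_raw": p_raw, "p_adj": p_adj}, index=matrix.data.index
    )
    return AnovaGate(table=table, alpha=alpha)


def day_profiles(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    genes=None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-gene mean expression per day, optionally z-scored across days.

    Replicates are averaged within each day; standardization removes level
    so that profile shape drives clustering.
    """
    annotation.check_matches(matrix)
    groups = annotation.groups("condition")
    days = sorted(groups, key=lambda key: float(str(key[0]).lstrip("d")))
    data = matrix.data if genes is None else matrix.data.loc[list(genes)]
    prof = pd.DataFrame(
        {key[0]: data[groups[key]].mean(axis=1) for key in days}, index=data.index
    )
    if standardize:
        mu = prof.mean(axis=1)
        sd = prof.std(axis=1, ddof=0)
        if np.any(sd == 0):
            bad = prof.index[sd == 0].tolist()
            raise ValidationError(f"flat day profile(s), cannot standardize: {bad[:5]}")
        prof = prof.sub(mu, axis=0).div(sd, axis=0)
    return prof


@dataclass
class ConsensusResult:
    """Consensus matrices over a K range, the chosen K, the gene assignment
    and per-cluster mean +/- sd day profiles."""

    consensus: dict  # K -> genes x genes ndarray in [0, 1]
    areas: dict  # K -> area under the consensus CDF
    delta_areas: dict  # K -> relative increase in area
    chosen_k: int  # number of substantive clusters in the selected cut
    k_star: int  # cut level selected by the delta-area plateau rule
    assignment: dict  # gene -> cluster id in 1..chosen_k
    gene_ids: list
    profiles: pd.DataFrame | None = None  # (cluster, day) mean/sd, filled later
    member_counts: dict = field(default_factory=dict)

    def assignment_for(self, K: int) -> dict:
        """Final assignment obtained by cutting the consensus tree at K."""
        return _assign_from_consensus(self.consensus[K], self.gene_ids, K)


def _consensus_cdf_area(C: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = C.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(C[iu])
    if vals.size == 0:
        return 0.0
    # area of the step CDF over [0, 1]
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.searchsorted(vals, xs, side="right") / vals.size
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_cluster(
    profiles: pd.DataFrame,
    k_range=range(2, 7),
    n_resamples: int = 250,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    inner: str = "hierarchical",
    plateau_threshold: float = 0.1,
    min_cluster_size: int = 3,
) -> ConsensusResult:
    """Consensus clustering of gated gene day-profiles.

    For each resample, genes are subsampled without replacement and
    clustered into K groups (average-linkage hierarchical on Pearson
    distance by default; k-means optional).  consensus(i, j) is the number
    of times i and j co-clustered divided by the number of times they were
    co-sampled.  The final assignment cuts an average-linkage tree of
    (1 - consensus) at the cut level ``k_star``: the largest K whose
    relative increase in area under the consensus CDF is at least
    ``plateau_threshold``.  A stable singleton (or any cluster smaller than
    ``min_cluster_size``) in that cut is an outlier, not a cluster:
    ``chosen_k`` counts only the substantive clusters, and outlier genes
    are reassigned to the substantive cluster they most often co-cluster
    with.
    """
    k_range = sorted(set(int(k) for k in k_range))
    genes = list(profiles.index)
    n = len(genes)
    if not k_range or min(k_range) < 2 or max(k_range) > max(n // 5, 2):
        raise ValidationError(
            f"K range {k_range} outside [2, n_genes/5] for {n} gated genes"
        )
    if not (0 < subsample_fraction <= 1):
        raise ValidationError("subsample_fraction must be in (0, 1]")
    X = profiles.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample_fraction * n)), max(k_range) + 1)

    consensus: dict = {}
    areas: dict = {}
    for K in k_range:
        hits = np.zeros((n, n))
        tries = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            sub = X[idx]
            labels_sub = _cluster_once(sub, K, inner, rng)
            tries[np.ix_(idx, idx)] += 1.0
            for c in range(1, K + 1):
                members = idx[labels_sub == c]
                hits[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(tries > 0, hits / np.where(tries > 0, tries, 1.0), 0.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
        consensus[K] = C
        areas[K] = _consensus_cdf_area(C)

    delta_areas: dict = {}
    prev = None
    for K in k_range:
        if prev is None:
            delta_areas[K] = areas[K]
        else:
            delta_areas[K] = (areas[K] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = K

    k_star = k_range[0]
    for K in k_range[1:]:
        if delta_areas[K] >= plateau_threshold:
            k_star = K

    raw = _assign_from_consensus(consensus[k_star], genes, k_star)
    raw_counts = np.bincount(list(raw.values()))[1:]
    substantive = [c + 1 for c, size in enumerate(raw_counts)
                   if size >= min_cluster_size]
    if not substantive:  # degenerate cut: keep it as-is
        substantive = list(range(1, k_star + 1))
    C_star = consensus[k_star]
    gene_pos = {g: i for i, g in enumerate(genes)}
    members = {c: [gene_pos[g] for g, cc in raw.items() if cc == c]
               for c in substantive}
    relabel = {c: i + 1 for i, c in enumerate(substantive)}
    assignment: dict = {}
    for gene, c in raw.items():
        if c in relabel:
            assignment[gene] = relabel[c]
        else:
            # outlier gene: nearest substantive cluster by mean consensus
            i = gene_pos[gene]
            best = max(
                substantive,
                key=lambda c2: (float(np.mean(C_star[i, members[c2]])), -c2),
            )
            assignment[gene] = relabel[best]
    chosen_k = len(substantive)
    counts: dict = {}
    for c in assignment.values():
        counts[c] = counts.get(c, 0) + 1
    return ConsensusResult(
        consensus=consensus,
        areas=areas,
        delta_areas=delta_areas,
        chosen_k=chosen_k,
        k_star=k_star,
        assignment=assignment,
        gene_ids=genes,
        member_counts=counts,
    )


def _assign_from_consensus(C: np.ndarray, genes, K: int) -> dict:
    """Cut an average-linkage tree of (1 - consensus) at K clusters."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    flat = fcluster(Z, t=K, criterion="maxclust")
    # relabel clusters by first appearance for determinism
    relabel: dict = {}
    for c in flat:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    return {gene: relabel[c] for gene, c in zip(genes, flat)}


def _cluster_once(X: np.ndarray, K: int, inner: str, rng: np.random.Generator) -> np.ndarray:
    if inner == "hierarchical":
        D = pearson_distance(X)
        Z = average(squareform(D, checks=False))
        return fcluster(Z, t=K, criterion="maxclust")
    if inner == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31 - 1)))
        return km.fit_predict(X) + 1
    raise ValidationError(f"unknown inner clustering algorithm {inner!r}")


def cluster_profiles(
    assignment: dict,
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
) -> pd.DataFrame:
    """Per-cluster mean and sd trajectories over days, plus member counts.

    Values are per-gene replicate-averaged day means; sd is across member
    genes within a cluster (0 for single-gene clusters).
    """
    if not assignment:
        raise ValidationError("empty assignment")
    prof = day_profiles(matrix, annotation, genes=list(assignment), standardize=False)
    clusters = sorted(set(assignment.values()))
    rows = []
    for c in clusters:
        members = [g for g, cc in assignment.items() if cc == c]
        if not members:
            raise ValidationError(f"cluster {c} has no members")
        block = prof.loc[members]
        for day in prof.columns:
            rows.append(
                {
                    "cluster": c,
                    "day": day,
                    "mean": float(block[day].mean()),
                    "sd": float(block[day].std(ddof=0)),
                    "n_genes": len(members),
                }
            )
    return pd.DataFrame(rows)
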