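"""Per-fraction differential expression with an empirical-Bayes moderated t.

For each (tissue, fraction) the CR-vs-GF contrast is tested gene-wise with a
moderated t-statistic: the per-gene residual variance ``s_g^2`` (pooled over
the two groups, ``d_g = n_a + n_b - 2`` df) is shrunk toward a prior variance
``s0^2`` carrying ``d0`` prior degrees of freedom,

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_mod     = mean_diff / sqrt(s_tilde^2 * (1/n_a + 1/n_b))

with ``t_mod ~ t(d0 + d_g)`` under the null (standard normal when
``d0 = inf``).  The hyperparameters (d0, s0^2) are estimated by moment
matching of ``log s_g^2`` under a scaled-F model, using digamma/trigamma
identities.  P-values are corrected per contrast with Benjamini-Hochberg and
the four fraction-level significant sets are partitioned into Venn regions
to quantify site specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ModeratedTPrior",
    "ContrastResult",
    "VennPartition",
    "SpecificitySummary",
    "fit_variance_prior",
    "moderated_t_contrast",
    "benjamini_hochberg",
    "significant_sets",
    "specificity_summary",
    "specificity_from_counts",
]


@dataclass(frozen=True)
class ModeratedTPrior:
    """Empirical-Bayes hyperparameters: prior df ``d0`` (may be ``inf``) and
    prior variance ``s0_sq`` in squared log2 units."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValidationError(f"d0 must be positive, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValidationError(f"s0_sq must be positive, got {self.s0_sq}")


@dataclass
class ContrastResult:
    """Per-gene results of one two-group contrast (group A minus group B,
    by convention CR minus GF)."""

    table: pd.DataFrame  # columns: mean_diff, s_g_sq, s_tilde_sq, t_mod, df_total, p_raw, p_adj
    prior: ModeratedTPrior
    group_a: list = field(default_factory=list)
    group_b: list = field(default_factory=list)

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)

    def significant(self, alpha: float = 0.001) -> set:
        return set(self.table.index[self.table["p_adj"] < alpha])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        raise ValidationError(f"trigamma inverse needs positive input, got {x}")
    # asymptotic bounds: trigamma(y) ~ 1/y + 1/(2y^2) for large y; ~ 1/y^2 near 0
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s_g_sq: np.ndarray, d_g: float) -> ModeratedTPrior:
    """Estimate (d0, s0_sq) from per-gene residual variances.

    Under the scaled-F model ``s_g^2 ~ s0^2 * F(d_g, d0)``, the log variances
    satisfy moment identities in digamma/trigamma; the excess dispersion of
    ``log s_g^2`` beyond ``trigamma(d_g/2)`` identifies ``d0``.  When no
    excess dispersion remains the prior df is infinite and ``s0^2`` is the
    mean of the observed variances.
    """
    s_g_sq = np.asarray(s_g_sq, dtype=float)
    if d_g < 1:
        raise ValidationError(f"residual df must be >=1, got {d_g}")
    positive = s_g_sq[s_g_sq > 0]
    if positive.size == 0:
        raise ValidationError("all residual variances are zero; cannot fit prior")
    if positive.size < 50:
        logger.warning(
            "fitting variance prior on only %d genes; estimate is unstable",
            positive.size,
        )
    z = np.log(positive)
    e = z - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_mean = float(e.mean())
    if positive.size < 2:
        excess = 0.0
    else:
        e_var = float(e.var(ddof=1))
        # finite-sample correction as in the standard empirical-Bayes fit
        n = positive.size
        excess = e_var * (n - 1) / n - float(special.polygamma(1, d_g / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
        return ModeratedTPrior(d0=d0, s0_sq=s0_sq)
    return ModeratedTPrior(d0=math.inf, s0_sq=float(positive.mean()))


def moderated_t_contrast(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a,
    group_b,
    prior: ModeratedTPrior | None = None,
) -> ContrastResult:
    """Moderated t-test of group A minus group B for every gene.

    ``group_a`` / ``group_b`` are either explicit sample-id lists or factor
    dictionaries understood by :meth:`SampleAnnotation.samples_where`
    (e.g. ``dict(tissue="ileum", fraction="tip", condition="CR")``).
    The prior is fitted from this contrast's pooled variances when not given.
    """
    samples_a = _resolve_group(annotation, group_a)
    samples_b = _resolve_group(annotation, group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(
            f"each group needs >=2 samples (got {len(samples_a)} and {len(samples_b)})"
        )
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValidationError(f"groups must be disjoint; shared samples: {sorted(overlap)[:5]}")

    A = matrix.data[samples_a].to_numpy(dtype=float)
    B = matrix.data[samples_b].to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]
    d_g = n_a + n_b - 2

    mean_diff = A.mean(axis=1) - B.mean(axis=1)
    ss_a = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s_g_sq = (ss_a + ss_b) / d_g

    if prior is None:
        prior = fit_variance_prior(s_g_sq, d_g)

    if math.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_g_sq, prior.s0_sq)
        df_total = math.inf
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d_g * s_g_sq) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g

    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), 0.0)
    # degenerate genes: zero variance everywhere and zero difference
    degenerate = (se == 0) & (mean_diff == 0)
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_raw = np.where(degenerate, 1.0, p_raw)
    p_adj = benjamini_hochberg(p_raw)

    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "s_g_sq": s_g_sq,
            "s_tilde_sq": s_tilde_sq,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=matrix.data.index,
    )
    return ContrastResult(table=table, prior=prior, group_a=samples_a, group_b=samples_b)


def _resolve_group(annotation: SampleAnnotation, group) -> list:
    if isinstance(group, dict):
        samples = annotation.samples_where(**group)
        if not samples:
            raise ValidationError(f"no samples match factors {group}")
        return samples
    return list(group)


def benjamini_hochberg(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``p_adj_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the sorted
    p-values, mapped back to the original order; monotone in ``p_raw``.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][:5]
        raise ValidationError(f"p-values outside [0,1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class VennPartition:
    """Significant gene sets per (tissue, fraction) and their Venn regions."""

    sets: dict  # label -> set of gene ids
    alpha: float = 0.001

    @property
    def labels(self) -> list:
        return list(self.sets)

    def union(self) -> set:
        out: set = set()
        for s in self.sets.values():
            out |= s
        return out

    def regions(self) -> dict:
        """Mapping frozenset of labels -> genes present in exactly those sets."""
        labels = self.labels
        out: dict = {}
        for r in range(1, len(labels) + 1):
            for combo in combinations(labels, r):
                inside = set.intersection(*(self.sets[l] for l in combo)) if combo else set()
                outside: set = set()
                for l in labels:
                    if l not in combo:
                        outside |= self.sets[l]
                out[frozenset(combo)] = inside - outside
        return out

    def region_counts(self) -> dict:
        return {key: len(genes) for key, genes in self.regions().items()}

    def exclusive_sets(self) -> dict:
        regions = self.regions()
        return {label: regions[frozenset([label])] for label in self.labels}

    def exclusive_counts(self) -> dict:
        return {label: len(genes) for label, genes in self.exclusive_sets().items()}


def significant_sets(contrasts: dict, alpha: float = 0.001) -> VennPartition:
    """Gate each fraction's contrast at adjusted p < alpha and partition.

    ``contrasts`` maps a fraction label (e.g. ``("ileum", "crypt")``) to its
    :class:`ContrastResult`; all contrasts must share the gene universe.
    """
    universes = {frozenset(c.gene_ids) for c in contrasts.values()}
    if len(universes) > 1:
        raise ValidationError("contrasts do not share a common gene universe")
    sets = {label: contrast.significant(alpha) for label, contrast in contrasts.items()}
    return VennPartition(sets=sets, alpha=alpha)


@dataclass(frozen=True)
class SpecificitySummary:
    n_specific: int
    n_total: int
    percent_specific: float | None  # None when the union is empty

    def __iter__(self):
        return iter((self.n_specific, self.n_total, self.percent_specific))


def specificity_summary(partition: VennPartition) -> SpecificitySummary:
    """Fraction of regulated genes confined to a single fraction's region.

    ``n_specific`` sums the exclusive Venn regions, ``n_total`` is the union
    size, and the percentage is rounded to the nearest integer.
    """
    n_total = len(partition.union())
    n_specific = sum(partition.exclusive_counts().values())
    if n_total == 0:
        return SpecificitySummary(0, 0, None)
    return SpecificitySummary(n_specific, n_total, round(100.0 * n_specific / n_total))


def specificity_from_counts(exclusive_counts, n_total: int) -> SpecificitySummary:
    """Specificity summary from printed per-fraction exclusive counts and a
    known union size (useful when only tabulated counts are available)."""
    n_specific = int(sum(exclusive_counts))
    if n_total == 0:
        return SpecificitySummary(0, 0, None)
    if n_specific > n_total:
        raise ValidationError("exclusive counts exceed the union size")
    return SpecificitySummary(n_specific, n_total, round(100.0 * n_specific / n_total))
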