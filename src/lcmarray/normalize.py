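"""Between-sample normalization of expression matrices.

Quantile normalization forces every sample onto a common distribution: the
across-sample mean of order statistics.  Tied values within a sample receive
the mean of their tied target order statistics, so the operation is
rank-based and deterministic.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix, ValidationError

__all__ = ["quantile_normalize", "log2_if_needed"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize so every sample shares the same value distribution.

    The target distribution is the mean, across samples, of the per-sample
    order statistics.  Within a sample, a run of tied values is mapped to
    the mean of the target values at its tied ranks.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs >=2 samples")
    X = matrix.values
    n_genes, n_samples = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    target = sorted_vals.mean(axis=1)

    out = np.empty_like(X)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        assigned = target.copy()
        # average target over runs of tied input values
        i = 0
        while i < n_genes:
            k = i + 1
            while k < n_genes and col_sorted[k] == col_sorted[i]:
                k += 1
            if k - i > 1:
                assigned[i:k] = target[i:k].mean()
            i = k
        out[order[:, j], j] = assigned
    return matrix.with_values(out, note="quantile_normalize")


def log2_if_needed(
    matrix: ExpressionMatrix, threshold: float = 50.0, force: bool | None = None
) -> ExpressionMatrix:
    """Apply log2 when the matrix looks linear-scale (max above ``threshold``).

    ``force=True`` always transforms, ``force=False`` never does; by default
    the maximum value decides.  The decision is recorded in the result's
    provenance.
    """
    X = matrix.values
    apply = force if force is not None else bool(X.size and X.max() > threshold)
    if not apply:
        return matrix.with_values(X, note="log2_if_needed: left unchanged")
    nonpos = np.argwhere(X <= 0)
    if len(nonpos):
        cells = [
            (matrix.gene_ids[i], matrix.sample_ids[j]) for i, j in nonpos[:5]
        ]
        raise ValidationError(
            f"log2 transform requires positive values; offending cells: {cells}"
        )
    return matrix.with_values(np.log2(X), note="log2_if_needed: applied log2")
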