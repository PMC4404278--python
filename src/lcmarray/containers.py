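"""Core in-memory containers shared across the pipeline.

The pipeline operates on a gene x sample matrix of log2 expression
intensities together with a per-sample annotation table describing the
crossed study design: tissue (ileum / colon), epithelial fraction
(tip / crypt) and either bacterial status (GF / CR) or day of
colonization (0, 1, 3, 5, 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "StudyDesign",
    "GroundTruth",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container or file violates its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 expression values.

    Wraps a :class:`pandas.DataFrame` with genes as the index and sample
    identifiers as columns.  Identifiers must be unique and all values
    finite.
    """

    data: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values.astype(float)).all():
            bad = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], list(self.provenance))

    def with_values(self, values: np.ndarray, note: str | None = None) -> "ExpressionMatrix":
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return ExpressionMatrix(df, prov)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)


# Annotation columns every sample table carries.
ANNOTATION_COLUMNS = ("tissue", "fraction", "condition", "replicate")


@dataclass
class SampleAnnotation:
    """Per-sample factor table: tissue, fraction, condition (status or day),
    replicate index.  Indexed by sample id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in annotation: {dups[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        if set(self.sample_ids) != set(matrix.sample_ids):
            extra = set(matrix.sample_ids) - set(self.sample_ids)
            missing = set(self.sample_ids) - set(matrix.sample_ids)
            raise ValidationError(
                f"annotation/matrix sample mismatch: matrix-only={sorted(extra)[:5]}, "
                f"annotation-only={sorted(missing)[:5]}"
            )

    def samples_where(self, **factors) -> list:
        mask = pd.Series(True, index=self.table.index)
        for key, value in factors.items():
            mask &= self.table[key] == value
        return list(self.table.index[mask])

    def groups(self, *factors: str) -> dict:
        """Mapping factor-level tuple -> list of sample ids."""
        out: dict = {}
        for key, sub in self.table.groupby(list(factors), sort=True, observed=True):
            if len(factors) == 1 and not isinstance(key, tuple):
                key = (key,)
            out[key] = list(sub.index)
        return out


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed design: tissues x fractions x conditions x replicates.

    ``conditions`` holds either bacterial-status labels (GF, CR) or
    colonization-day labels (0, 1, 3, 5, 7).
    """

    tissues: tuple
    fractions: tuple
    conditions: tuple
    replicates_per_group: int
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.tissues) * len(self.fractions) * len(self.conditions)

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.replicates_per_group

    @property
    def is_timecourse(self) -> bool:
        return all(str(c).lstrip("d").isdigit() for c in self.conditions)

    def sample_ids(self) -> list:
        return list(self.annotation().sample_ids)

    def annotation(self) -> SampleAnnotation:
        rows = []
        for tissue in self.tissues:
            for fraction in self.fractions:
                for condition in self.conditions:
                    for rep in range(1, self.replicates_per_group + 1):
                        sid = f"{tissue}_{fraction}_{condition}_r{rep}"
                        rows.append((sid, tissue, fraction, condition, rep))
        df = pd.DataFrame(
            rows, columns=["sample", *ANNOTATION_COLUMNS]
        ).set_index("sample")
        return SampleAnnotation(df)


@dataclass
class GroundTruth:
    """Planted truth of a synthetic experiment, used in recovery tests.

    regulated_genes
        (tissue, fraction) -> {gene id: log2 effect of CR vs GF}.  The key
        ``"shared"`` holds genes regulated in all tissue/fraction groups.
    cluster_assignments
        (tissue, fraction) -> {gene id: archetype id in 1..4}.
    enriched_terms
        fraction key -> set of term ids truly enriched.
    planted_motif_targets
        motif id -> {gene id: (start, strand)} of the planted consensus site.
    """

    regulated_genes: dict = field(default_factory=dict)
    cluster_assignments: dict = field(default_factory=dict)
    enriched_terms: dict = field(default_factory=dict)
    planted_motif_targets: dict = field(default_factory=dict)

    def all_regulated(self) -> set:
        out: set = set()
        for genes in self.regulated_genes.values():
            out |= set(genes)
        return out

    def regulated_in(self, tissue, fraction) -> set:
        specific = set(self.regulated_genes.get((tissue, fraction), {}))
        shared = set(self.regulated_genes.get("shared", {}))
        return specific | shared

    def to_jsonable(self) -> dict:
        return {
            "regulated_genes": {
                "|".join(k) if isinstance(k, tuple) else str(k): dict(v)
                for k, v in self.regulated_genes.items()
            },
            "cluster_assignments": {
                "|".join(k) if isinstance(k, tuple) else str(k): dict(v)
                for k, v in self.cluster_assignments.items()
            },
            "enriched_terms": {str(k): sorted(v) for k, v in self.enriched_terms.items()},
            "planted_motif_targets": {
                str(m): {g: list(pos) for g, pos in targets.items()}
                for m, targets in self.planted_motif_targets.items()
            },
        }
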