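"""Promoter scanning with position weight matrices (PWMs).

Regulator -> target maps are derived by scanning 1-kb promoter sequences
with PWMs: every window on both strands is scored as a log-odds sum in bits
against a background base distribution, and a gene is called a target of a
motif when some window reaches a caller-set fraction of the motif's maximum
attainable score.  A pseudocount is added to each matrix cell before column
normalization so that zero probabilities never produce infinite scores; N
bases contribute zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ValidationError
from .enrichment import RegulatorTargets

logger = logging.getLogger(__name__)

__all__ = ["MotifMatrix", "MotifHit", "log_odds_score", "scan_promoters", "reverse_complement"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PSEUDOCOUNT = 0.01
DEFAULT_BACKGROUND = np.full(4, 0.25)
COLUMN_SUM_TOL = 1e-6
MIN_MOTIF_LENGTH = 4


@dataclass
class MotifMatrix:
    """Per-position base-probability model of a binding motif.

    ``matrix`` has shape (length, 4) with columns ordered A, C, G, T; rows
    sum to 1.  ``background`` is the base distribution scores are measured
    against (uniform by default).
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"motif {self.id}: matrix must be length x 4")
        if len(self.matrix) < MIN_MOTIF_LENGTH:
            raise ValidationError(
                f"motif {self.id}: length {len(self.matrix)} < {MIN_MOTIF_LENGTH}"
            )
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > COLUMN_SUM_TOL):
            raise ValidationError(f"motif {self.id}: probability rows must sum to 1")
        if abs(self.background.sum() - 1.0) > COLUMN_SUM_TOL:
            raise ValidationError(f"motif {self.id}: background must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    def log_odds(self) -> np.ndarray:
        """(length, 4) log2-odds with pseudocount regularization."""
        probs = self.matrix + PSEUDOCOUNT
        probs = probs / probs.sum(axis=1, keepdims=True)
        return np.log2(probs / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold window: 0-based half-open [start, start+len) on
    the given promoter; strand '-' means the site lies on the reverse
    complement."""

    gene: str
    motif: str
    start: int
    end: int
    strand: str
    score: float


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def log_odds_score(window: str, motif: MotifMatrix) -> float:
    """Log2-odds score of one window: sum of log2(p_pos(base)/q(base));
    N bases contribute 0."""
    window = window.upper()
    if len(window) != len(motif):
        raise ValidationError(
            f"window length {len(window)} != motif length {len(motif)}"
        )
    lods = motif.log_odds()
    score = 0.0
    for pos, base in enumerate(window):
        if base == "N":
            continue
        if base not in BASE_INDEX:
            raise ValidationError(f"illegal base {base!r} at window position {pos}")
        score += lods[pos, BASE_INDEX[base]]
    return float(score)


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and N -> 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, lods: np.ndarray) -> np.ndarray:
    """Vectorized window scores: codes (L,), lods (w, 4) -> (L - w + 1,)."""
    w = lods.shape[0]
    L = codes.size
    if L < w:
        return np.empty(0)
    # pad a zero column for N (code 4)
    lods5 = np.hstack([lods, np.zeros((w, 1))])
    n_windows = L - w + 1
    scores = np.zeros(n_windows)
    for pos in range(w):
        scores += lods5[pos, codes[pos : pos + n_windows]]
    return scores


def scan_promoters(
    promoters: dict,
    motifs,
    threshold_fraction: float = 0.8,
) -> tuple:
    """Scan promoters with motifs on both strands.

    A gene is a target of a motif iff some window on either strand scores at
    least ``threshold_fraction`` times the motif's maximum attainable score.
    Returns ``(RegulatorTargets, list of MotifHit)``.  Promoters shorter
    than a motif are skipped for that motif with a warning.  Reverse-strand
    hit coordinates refer to the forward promoter sequence.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValidationError("threshold_fraction must be in (0, 1]")
    targets: dict = {m.id: set() for m in motifs}
    hits: list = []
    encoded = {gene: _encode(seq.upper()) for gene, seq in promoters.items()}
    for motif in motifs:
        lods = motif.log_odds()
        w = len(motif)
        cutoff = threshold_fraction * motif.max_score()
        for gene in sorted(promoters):
            codes = encoded[gene]
            L = codes.size
            if L < w:
                logger.warning(
                    "promoter %s (length %d) shorter than motif %s (length %d); skipped",
                    gene, L, motif.id, w,
                )
                continue
            fwd = _window_scores(codes, lods)
            rev_codes = _encode(reverse_complement(promoters[gene].upper()))
            rev = _window_scores(rev_codes, lods)
            hit_any = False
            for start in np.nonzero(fwd >= cutoff)[0]:
                hits.append(MotifHit(gene, motif.id, int(start), int(start) + w, "+",
                                     float(fwd[start])))
                hit_any = True
            for start_rc in np.nonzero(rev >= cutoff)[0]:
                # reflect onto forward coordinates: position p on the reverse
                # complement corresponds to [L - p - w, L - p) forward
                start = L - int(start_rc) - w
                hits.append(MotifHit(gene, motif.id, start, start + w, "-",
                                     float(rev[start_rc])))
                hit_any = True
            if hit_any:
                targets[motif.id].add(gene)
    hits.sort(key=lambda h: (h.motif, h.gene, h.start, h.strand))
    return RegulatorTargets(targets=targets, provenance="motif_scan"), hits
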