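"""Built-in similarity backend: deterministic Smith–Waterman scoring.

Desk-scale replacement for an external BLAST search. Raw local-alignment
scores (BLOSUM62, affine gaps) are used directly for ranking: the profiling
engines only consume the ordering and tie structure of a hit list, never the
score magnitude, so no bit-score conversion is applied. A gap of length k
costs ``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .core import GenomeCollection, Hit, HitList, sanitize_protein


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring parameters for the built-in backend.

    ``score_floor``: minimum raw score for a hit to be reported (0 reports
    every positive-scoring subject).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    score_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


DEFAULT_PARAMS = ScoringParams()


@lru_cache(maxsize=8)
def _local_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=2)
def _identity_aligner() -> Align.PairwiseAligner:
    # Global alignment used only to count identities; end gaps are scored so
    # terminal overhangs count as aligned columns.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def local_align_score(
    seq_a: str, seq_b: str, params: ScoringParams = DEFAULT_PARAMS
) -> float:
    """Optimal Smith–Waterman local alignment score (symmetric, >= 0)."""
    a = sanitize_protein(seq_a)
    b = sanitize_protein(seq_b)
    aligner = _local_aligner(params.matrix, params.gap_open, params.gap_extend)
    return float(aligner.score(a, b))


def global_align(seq_a: str, seq_b: str) -> Align.Alignment:
    """One optimal global (Needleman–Wunsch) alignment of two proteins."""
    a = sanitize_protein(seq_a)
    b = sanitize_protein(seq_b)
    return _identity_aligner().align(a, b)[0]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical residues over all aligned columns (end gaps counted)."""
    alignment = global_align(seq_a, seq_b)
    identities = alignment.counts().identities
    return identities / alignment.length


def rank_hits(
    query: str,
    query_seq: str,
    database: GenomeCollection,
    params: ScoringParams = DEFAULT_PARAMS,
) -> HitList:
    """Score the query against every database protein and rank the hits.

    Subjects scoring above the floor appear once each, sorted by descending
    score; equal scores keep database iteration order (stable sort). The
    query's self-hit is included whenever the query is in the database.
    """
    scored: list[Hit] = []
    for subject, seq in database.sequences.items():
        s = local_align_score(query_seq, seq, params)
        if s > params.score_floor:
            scored.append(
                Hit(query, subject, database.protein_index[subject], s, rank=1)
            )
    return HitList.from_unsorted(query, scored)
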