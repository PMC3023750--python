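"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the code it checks:
the alignment oracle is a naive quadratic-space Gotoh DP, the prefix oracle
scans every distinct score cutoff and scores tails through scipy's binomial
survival function, and the ORF oracle walks codons start-first instead of
stop-first.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.stats import binom

_LN10 = math.log(10.0)


def sw_score_dp(a: str, b: str, matrix: str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman optimal score, three-state affine DP over all cells.

    A gap of length k costs gap_open + (k - 1) * gap_extend.
    """
    sub = substitution_matrices.load(matrix)
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def log10_tail_scipy(y: int, n: int, p: float) -> float:
    """log10 P(X >= y) via scipy's binomial log-survival function."""
    if y == 0:
        return 0.0
    return min(0.0, float(binom.logsf(y - 1, n, p)) / _LN10)


def best_cutoff_exhaustive(scored_hits, labels: dict[str, bool], p: float):
    """Best (most negative) tail score over every distinct score cutoff.

    ``scored_hits``: list of (score, unit) sorted by non-increasing score,
    units being genomes (or sequences); duplicates of a unit count once.
    Returns the minimum over cutoffs of log10 P(X >= y), including the empty
    cutoff (0.0). Ties resolve toward the shallower cutoff by scan order.
    """
    cutoffs = sorted({s for s, _ in scored_hits}, reverse=True)
    best = 0.0
    for c in cutoffs:
        prefix = [u for s, u in scored_hits if s >= c]
        units = set(prefix)
        y = sum(labels[u] for u in units)
        score = log10_tail_scipy(y, len(units), p)
        if score < best:
            best = score
    return best


def orf_scan_all_starts(contig_id: str, seq: str, min_aa: int, max_aa: int,
                        starts=("ATG", "GTG", "TTG")):
    """Every start-to-next-stop ORF within bounds, walking starts forward."""
    stops = {"TAA", "TAG", "TGA"}
    length = len(seq)
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for offset in range(3):
            codons = [s[i:i + 3] for i in range(offset, length - 2, 3)]
            stop_idx = [i for i, c in enumerate(codons) if c in stops]
            for i, codon in enumerate(codons):
                if codon not in starts or "N" in codon:
                    continue
                nxt = next((k for k in stop_idx if k > i), None)
                if nxt is None:
                    continue
                aa_len = nxt - i
                if not (min_aa <= aa_len <= max_aa):
                    continue
                lo = offset + 3 * i
                hi = offset + 3 * (nxt + 1)
                pep = str(Seq(s[lo:hi]).translate(table=11)).rstrip("*")
                pep = "M" + pep[1:]
                if strand == "+":
                    coords = (lo + 1, hi)
                else:
                    coords = (length - hi + 1, length - lo)
                out.add((contig_id, strand, offset + 1, coords[0], coords[1], pep))
    return out
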