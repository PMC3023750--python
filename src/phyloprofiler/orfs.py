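"""Six-frame short-ORF detection, C-terminal motif scanning, and alignment
conservation statistics.

Ribosomally produced cofactor/bacteriocin precursors are short peptides that
gene callers routinely miss; scanning six-frame translations for open
reading frames in the precursor size range, then filtering on an invariant
C-terminal motif, recovers them directly from contigs. Translation uses the
bacterial/archaeal code (table 11) with the alternative starts GTG/TTG read
as Met when used as the initiator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .core import ColumnStats, ConservationProfile

_STOPS_T11 = {"TAA", "TAG", "TGA"}
DEFAULT_STARTS = frozenset({"ATG", "GTG", "TTG"})
_DNA = set("ACGTN")


@dataclass(frozen=True)
class OrfHit:
    """A short predicted peptide from a six-frame scan.

    Coordinates are 1-based inclusive on the forward strand and include the
    stop codon; ``frame`` is 1..3 within its strand. The peptide carries no
    stop symbol and its initiator is reported as M.
    """

    contig: str
    strand: str  # '+' or '-'
    frame: int
    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if (self.end - self.start + 1) % 3:
            raise ValueError("ORF span not divisible by 3")
        if len(self.peptide) != (self.end - self.start + 1) // 3 - 1:
            raise ValueError("peptide length inconsistent with coordinates")

    def extract_cds(self, contig_seq: str) -> str:
        """Nucleotide CDS (start codon through stop) in reading orientation."""
        sub = contig_seq[self.start - 1 : self.end]
        return str(Seq(sub).reverse_complement()) if self.strand == "-" else sub


def translate_cds(cds: str, table: int = 11) -> str:
    """Translate a stop-terminated CDS, forcing the initiator to M."""
    aa = str(Seq(cds).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    return ("M" + aa[1:]) if aa else aa


def six_frame_orfs(
    contig_id: str,
    contig_seq: str,
    min_aa: int = 20,
    max_aa: int = 120,
    table: int = 11,
    starts: frozenset[str] | set[str] = DEFAULT_STARTS,
    all_starts: bool = False,
) -> list[OrfHit]:
    """Enumerate start-to-stop ORFs in all six frames within length bounds.

    By default each stop codon yields at most one ORF per frame, anchored at
    the most upstream qualifying start after the previous in-frame stop
    (start-site predictions for short peptides are unreliable, so the longest
    form is reported); ``all_starts=True`` additionally emits every internal
    start within the bounds. ORFs lacking an in-frame stop before the contig
    end are excluded. Codons containing N translate to X and never qualify
    as starts or stops.
    """
    contig_seq = contig_seq.upper()
    bad = set(contig_seq) - _DNA
    if bad:
        raise ValueError(f"contig {contig_id!r}: invalid nucleotides {sorted(bad)}")
    if table != 11:
        raise ValueError("only translation table 11 is supported")
    length = len(contig_seq)
    hits: list[OrfHit] = []
    for strand in "+-":
        s = contig_seq if strand == "+" else str(Seq(contig_seq).reverse_complement())
        for offset in range(3):
            frame = offset + 1
            candidate_starts: list[int] = []  # codon indices since last stop
            n_codons = (length - offset) // 3
            for ci in range(n_codons):
                pos = offset + 3 * ci
                codon = s[pos : pos + 3]
                if codon in _STOPS_T11:
                    for sc in candidate_starts:
                        aa_len = ci - sc  # codons between start and stop
                        if not (min_aa <= aa_len <= max_aa):
                            continue
                        lo = offset + 3 * sc  # 0-based in strand coords
                        hi = pos + 3  # exclusive, includes stop codon
                        cds = s[lo:hi]
                        if strand == "+":
                            fstart, fend = lo + 1, hi
                        else:
                            fstart, fend = length - hi + 1, length - lo
                        hits.append(
                            OrfHit(
                                contig_id,
                                strand,
                                frame,
                                fstart,
                                fend,
                                translate_cds(cds, table),
                            )
                        )
                        if not all_starts:
                            break  # most upstream qualifying start only
                    candidate_starts = []
                elif codon in starts and "N" not in codon:
                    candidate_starts.append(ci)
    return hits


@dataclass(frozen=True)
class MotifSpec:
    """A C-terminal peptide motif.

    ``pattern`` is matched against the peptide end: uppercase residues are
    literal, lowercase ``x`` (or ``.``) matches any residue. With
    ``mode="suffix"`` the pattern must sit exactly ``<= max_distance``
    residues from the C-terminus (default 0: a true suffix);
    ``mode="pattern"`` is an alias kept for position-pattern specs written
    with explicit wildcards — the matching rule is identical.
    """

    pattern: str
    max_distance: int = 0
    mode: str = "suffix"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern is empty")
        if self.mode not in ("suffix", "pattern"):
            raise ValueError(f"unknown motif mode {self.mode!r}")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        self._regex()  # validate pattern characters eagerly

    def _regex(self) -> re.Pattern[str]:
        parts = []
        for ch in self.pattern:
            if ch in ("x", "."):
                parts.append(".")
            elif ch.isalpha() and ch.isupper():
                parts.append(re.escape(ch))
            else:
                raise ValueError(f"bad motif character {ch!r}")
        return re.compile("".join(parts) + ".{0,%d}$" % self.max_distance)

    def matches(self, peptide: str) -> bool:
        return self._regex().search(peptide) is not None


def scan_cterm_motif(orfs: Iterable[OrfHit], motif: MotifSpec) -> list[OrfHit]:
    """ORFs whose peptide carries the motif at the required C-terminal offset."""
    return [o for o in orfs if motif.matches(o.peptide)]


def scan_contigs(
    contigs: dict[str, str] | str | Path,
    motif: MotifSpec | None = None,
    min_aa: int = 20,
    max_aa: int = 120,
    all_starts: bool = False,
) -> list[OrfHit]:
    """Six-frame scan over contigs (dict or FASTA path), optionally motif-filtered."""
    if isinstance(contigs, (str, Path)):
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(contigs), "fasta")}
    hits: list[OrfHit] = []
    for cid, seq in contigs.items():
        hits.extend(six_frame_orfs(cid, seq, min_aa=min_aa, max_aa=max_aa, all_starts=all_starts))
    return scan_cterm_motif(hits, motif) if motif is not None else hits


def write_orf_tsv(hits: Sequence[OrfHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstrand\tframe\tstart\tend\tpeptide\n")
        for h in hits:
            fh.write(f"{h.contig}\t{h.strand}\t{h.frame}\t{h.start}\t{h.end}\t{h.peptide}\n")


_GAPS = {"-", "."}


def column_conservation(msa: Sequence[str] | str | Path) -> ConservationProfile:
    """Per-column dominant residue and conservation of an alignment.

    Accepts aligned rows or an aligned-FASTA path. The dominant fraction is
    computed over non-gap rows; a column is invariant iff that fraction is 1.
    Ties on the dominant residue resolve alphabetically.
    """
    if isinstance(msa, (str, Path)):
        rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(msa), "fasta")]
    else:
        rows = [r.upper() for r in msa]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    columns = []
    for j in range(width):
        residues = [r[j] for r in rows if r[j] not in _GAPS]
        if not residues:
            columns.append(ColumnStats(dominant="-", fraction=0.0, n_nongap=0))
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        dominant = min(counts, key=lambda c: (-counts[c], c))
        columns.append(
            ColumnStats(dominant, counts[dominant] / len(residues), len(residues))
        )
    return ConservationProfile(columns=columns, n_sequences=len(rows))
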