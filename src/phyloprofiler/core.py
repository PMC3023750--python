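"""Shared domain types and file I/O for comparative-genomics profiling.

A *genome collection* is a set of proteomes with an explicit protein-to-genome
map. A *phylogenetic profile* labels every genome YES or NO for some trait
(e.g. "encodes the marker gene cluster"). Ranked similarity hit lists, read
from BLAST tabular output or produced by the built-in aligner, are the third
ingredient; together these drive the profiling engines.

File conventions: proteomes and contigs are FASTA; the genome map and trait
profile are two-column TSV with a header line; hit tables use the 12-column
BLAST tabular (outfmt 6) dialect; result tables are TSV with ``#``-prefixed
metadata lines before the header.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = set(STANDARD_AA) | {"X"}


def sanitize_protein(seq: str, name: str = "") -> str:
    """Uppercase a protein sequence and map non-standard letters to X."""
    seq = seq.upper()
    if not seq:
        raise ValueError(f"empty protein sequence {name!r}")
    bad = set(seq) - _VALID_AA
    if bad:
        warnings.warn(
            f"sequence {name!r}: non-standard residues {sorted(bad)} mapped to X",
            stacklevel=2,
        )
        seq = "".join(c if c in _VALID_AA else "X" for c in seq)
    return seq


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeCollection:
    """Proteomes plus a protein-to-genome map.

    Attributes
    ----------
    genomes : list of genome identifiers (unique, order preserved)
    protein_index : protein identifier -> genome identifier
    sequences : protein identifier -> amino-acid sequence
    """

    genomes: list[str]
    protein_index: dict[str, str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome identifiers")
        known = set(self.genomes)
        for prot, gen in self.protein_index.items():
            if gen not in known:
                raise ValueError(f"protein {prot!r} maps to unknown genome {gen!r}")
        for prot in self.sequences:
            if prot not in self.protein_index:
                raise ValueError(f"sequence {prot!r} has no genome mapping")
            if not self.sequences[prot]:
                raise ValueError(f"empty sequence for protein {prot!r}")

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def proteins_of(self, genome: str) -> list[str]:
        if genome not in set(self.genomes):
            raise KeyError(f"unknown genome {genome!r}")
        return [p for p, g in self.protein_index.items() if g == genome]


@dataclass(frozen=True)
class PhyloProfile:
    """YES/NO trait labels over a genome collection.

    ``p = K/N`` is the trait prevalence, the success probability of the
    binomial null model used by the profiling score.
    """

    labels: Mapping[str, bool]

    def __post_init__(self) -> None:
        k = self.yes_count
        if k == 0 or k == len(self.labels):
            raise ValueError(
                f"uninformative profile: {k} YES of {len(self.labels)} genomes"
            )

    @property
    def yes_count(self) -> int:
        return sum(self.labels.values())

    @property
    def total(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return self.yes_count / self.total

    def is_yes(self, genome: str) -> bool:
        return self.labels[genome]


@dataclass(frozen=True)
class Hit:
    """One ranked similarity hit of a query protein."""

    query: str
    subject: str
    subject_genome: str
    score_bits: float
    rank: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.score_bits):
            raise ValueError(f"non-finite score for hit {self.subject!r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass
class HitList:
    """Hits of one query, sorted by non-increasing score, ranks 1..n.

    Equal-score hits form contiguous tie blocks; cutoff searches treat a
    tie block as atomic.
    """

    query: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, h in enumerate(self.hits):
            if h.rank != i + 1:
                raise ValueError(f"ranks not consecutive at position {i}")
            if i and h.score_bits > self.hits[i - 1].score_bits:
                raise ValueError("hits not sorted by non-increasing score")

    def __len__(self) -> int:
        return len(self.hits)

    def tie_blocks(self) -> Iterator[list[Hit]]:
        """Yield maximal runs of equal-score hits, best first."""
        block: list[Hit] = []
        for h in self.hits:
            if block and h.score_bits != block[-1].score_bits:
                yield block
                block = []
            block.append(h)
        if block:
            yield block

    @classmethod
    def from_unsorted(cls, query: str, hits: Iterable[Hit]) -> "HitList":
        """Stable-sort hits by descending score and reassign ranks."""
        ordered = sorted(hits, key=lambda h: -h.score_bits)
        renum = [
            Hit(h.query, h.subject, h.subject_genome, h.score_bits, i + 1)
            for i, h in enumerate(ordered)
        ]
        return cls(query, renum)


@dataclass(frozen=True)
class PPPResult:
    """Optimal-cutoff profiling result for one protein.

    ``yes``/``total`` count distinct trait-positive/all genomes at the best
    cutoff, ``depth`` counts protein hits traversed to reach it, and
    ``score`` is the log10 binomial upper-tail probability (<= 0; 0 means no
    cutoff beats the empty prefix).
    """

    query: str
    yes: int
    total: int
    depth: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.yes <= self.total <= self.depth):
            raise ValueError(f"inconsistent counts for {self.query!r}")
        if self.score > 0:
            raise ValueError("profiling score must be <= 0")


@dataclass(frozen=True)
class ColumnStats:
    dominant: str
    fraction: float
    n_nongap: int

    @property
    def invariant(self) -> bool:
        return self.fraction == 1.0 and self.n_nongap > 0


@dataclass
class ConservationProfile:
    """Per-column conservation of a multiple sequence alignment."""

    columns: list[ColumnStats]
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def invariant_in_last(self, m: int) -> int:
        """Number of invariant columns among the last ``m`` columns."""
        return sum(c.invariant for c in self.columns[-m:])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_two_column_tsv(path: str | Path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty {what} file {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            rows.append((parts[0], parts[1]))
    if not rows:
        raise ValueError(f"no data rows in {what} file {path}")
    return rows


def read_fasta_collection(
    fasta_paths: Sequence[str | Path] | str | Path,
    genome_map: str | Path,
) -> GenomeCollection:
    """Load proteome FASTA file(s) and a protein→genome map TSV.

    Genome identity is taken from the map file only, never parsed from FASTA
    headers. Every FASTA record must appear in the map; duplicate record
    identifiers are rejected.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    mapping = dict(_read_two_column_tsv(genome_map, "genome map"))
    genomes: list[str] = []
    seen_gen: set[str] = set()
    for gen in mapping.values():
        if gen not in seen_gen:
            seen_gen.add(gen)
            genomes.append(gen)

    sequences: dict[str, str] = {}
    index: dict[str, str] = {}
    n_records = 0
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            n_records += 1
            if rec.id in sequences:
                raise ValueError(f"duplicate protein identifier {rec.id!r}")
            if rec.id not in mapping:
                raise ValueError(
                    f"record {rec.id!r} in {path} has no genome mapping"
                )
            sequences[rec.id] = sanitize_protein(str(rec.seq), rec.id)
            index[rec.id] = mapping[rec.id]
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {list(map(str, fasta_paths))}")
    return GenomeCollection(genomes=genomes, protein_index=index, sequences=sequences)


def write_fasta_collection(
    collection: GenomeCollection, fasta_path: str | Path, map_path: str | Path
) -> None:
    recs = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in collection.sequences.items()
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    with open(map_path, "w") as fh:
        fh.write("protein\tgenome\n")
        # grouped by genome so a re-read preserves the genome ordering
        for genome in collection.genomes:
            for pid in collection.proteins_of(genome):
                fh.write(f"{pid}\t{genome}\n")


_TRUTHY = {"YES", "Y", "TRUE", "1"}
_FALSY = {"NO", "N", "FALSE", "0"}


def read_profile(path: str | Path, collection: GenomeCollection) -> PhyloProfile:
    """Read a genome trait table (genome<TAB>YES|NO) against a collection.

    Every genome of the collection must be labelled exactly once; unknown or
    missing genomes, and uninformative all-YES/all-NO profiles, are errors.
    """
    labels: dict[str, bool] = {}
    known = set(collection.genomes)
    for genome, value in _read_two_column_tsv(path, "trait profile"):
        if genome not in known:
            raise ValueError(f"profile labels unknown genome {genome!r}")
        if genome in labels:
            raise ValueError(f"genome {genome!r} labelled more than once")
        v = value.strip().upper()
        if v in _TRUTHY:
            labels[genome] = True
        elif v in _FALSY:
            labels[genome] = False
        else:
            raise ValueError(f"unrecognized trait label {value!r} for {genome!r}")
    missing = known - set(labels)
    if missing:
        raise ValueError(f"genomes without trait label: {sorted(missing)}")
    return PhyloProfile(labels)


def write_profile(profile: PhyloProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\ttrait\n")
        for genome, yes in profile.labels.items():
            fh.write(f"{genome}\t{'YES' if yes else 'NO'}\n")


def read_search_tabular(
    source: str | Path | TextIO,
    collection: GenomeCollection,
    on_unknown_subject: str = "error",
) -> list[HitList]:
    """Parse 12-column BLAST tabular (outfmt 6) into per-query hit lists.

    Hits are grouped by query in order of first appearance, stably re-sorted
    by descending bit score, and ranked. Subject genomes are resolved through
    the collection's protein index; ``on_unknown_subject`` chooses between a
    hard error and skip-with-warning.
    """
    if on_unknown_subject not in ("error", "skip"):
        raise ValueError("on_unknown_subject must be 'error' or 'skip'")
    close = False
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source)
        close = True
    else:
        fh = source
    per_query: dict[str, list[tuple[str, str, float]]] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            query, subject = parts[0], parts[1]
            try:
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad bit score {parts[11]!r}") from exc
            if subject not in collection.protein_index:
                if on_unknown_subject == "skip":
                    warnings.warn(
                        f"line {lineno}: subject {subject!r} not in collection, skipped"
                    )
                    continue
                raise ValueError(f"line {lineno}: subject {subject!r} not in collection")
            per_query.setdefault(query, []).append(
                (subject, collection.protein_index[subject], bitscore)
            )
    finally:
        if close:
            fh.close()
    out = []
    for query, rows in per_query.items():
        hits = [
            Hit(query, subj, gen, score, rank=i + 1)
            for i, (subj, gen, score) in enumerate(rows)
        ]
        out.append(HitList.from_unsorted(query, hits))
    return out


def write_results_tsv(
    results: Sequence[PPPResult],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    annotations: Mapping[str, str] | None = None,
) -> None:
    """Write profiling results as TSV mirroring the #Yes/#Total/#Depth/Score layout."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("query\tyes\ttotal\tdepth\tscore")
        fh.write("\tannotation\n" if annotations else "\n")
        for r in results:
            line = f"{r.query}\t{r.yes}\t{r.total}\t{r.depth}\t{r.score:.6f}"
            if annotations:
                line += f"\t{annotations.get(r.query, '')}"
            fh.write(line + "\n")


def read_results_tsv(path: str | Path) -> list[PPPResult]:
    results = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("query\t") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            results.append(
                PPPResult(parts[0], int(parts[1]), int(parts[2]), int(parts[3]), float(parts[4]))
            )
    return results
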