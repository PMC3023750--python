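"""Synthetic genome collections with planted comparative-genomics structure.

The generator emulates the data regime the profiling engines assume, at desk
scale: a minority of genomes carry a marker gene system (one single-copy
marker family per cluster gene, present in all and only trait-positive
genomes); *dependent* paralog families occur only in trait-positive genomes,
with variable copy number, and carry a short diagnostic subsequence window
whose residues differ from an otherwise-interchangeable *sister* clade found
in every genome; *background* families are present everywhere and carry no
trait signal. Trait-positive contigs additionally carry short precursor
genes with a conserved 23-residue C-terminal region ending in an invariant
suffix, plus decoy short genes with that region shuffled.

Within a family, sequences are independent substitution-mutated copies of a
family ancestor, so two members share roughly ``identity**2`` pairwise
identity outside any fixed window. No indels, tree structure, or codon-usage
realism are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import (
    GenomeCollection,
    PhyloProfile,
    write_fasta_collection,
    write_profile,
    STANDARD_AA,
)
from .orfs import MotifSpec

# 23-residue conserved C-terminal region template for planted precursors;
# lowercase x marks the variable positions. Seven of the last eight residues
# (ILD.CGVY) are invariant, the final four (CGVY) always.
CTERM_TEMPLATE = "DVNAETSxLEHGSQPILDxCGVY"
DEFAULT_PRECURSOR_MOTIF = MotifSpec(pattern="ILDxCGVY", max_distance=0)

_AA = np.frombuffer(STANDARD_AA.encode(), dtype="S1")
_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

# aa -> codon used when reverse-translating planted peptides (table 11)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def _replacement_matrix() -> np.ndarray:
    """P(replacement | original) over the 19 other residues, weighted by
    BLOSUM62 (weight 2**(score/2)), so mutated positions prefer plausible
    substitutions."""
    b62 = substitution_matrices.load("BLOSUM62")
    probs = np.zeros((20, 20))
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            if i != j:
                probs[i, j] = 2.0 ** (b62[a, b] / 2.0)
        probs[i] /= probs[i].sum()
    return probs


_REPLACE = _replacement_matrix()


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(STANDARD_AA))[rng.integers(0, 20, size=length)])


def mutate_sequence(
    ancestor: str, target_identity: float, seed: int | np.random.Generator
) -> str:
    """Substitution-mutated copy of an ancestor at a controlled identity.

    Exactly ``round((1 - target_identity) * len)`` positions, chosen
    uniformly without replacement, receive a BLOSUM62-weighted replacement
    residue different from the original, so the realized identity equals the
    target up to rounding. Deterministic for a fixed seed.
    """
    if not ancestor:
        raise ValueError("empty ancestor sequence")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    rng = _as_rng(seed)
    n = len(ancestor)
    k = round((1.0 - target_identity) * n)
    if k == 0:
        return ancestor
    positions = rng.choice(n, size=k, replace=False)
    out = list(ancestor)
    for pos in positions:
        orig = _AA_INDEX.get(out[pos], None)
        if orig is None:  # X or similar: replace uniformly
            out[pos] = STANDARD_AA[rng.integers(0, 20)]
        else:
            out[pos] = STANDARD_AA[rng.choice(20, p=_REPLACE[orig])]
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic genome collection.

    Defaults model a sparsely distributed trait at desk scale: 40 genomes
    with a 10% trait prevalence (four trait-positive genomes), one marker
    cluster of 4 single-copy families, three dependent/sister family pairs,
    and background families filling each proteome to ~160 proteins. The
    ``sparse`` preset keeps the ~3% prevalence of the rarest published
    profiles by enlarging the collection so that at least four genomes are
    trait-positive.
    """

    seed: int = 0
    n_genomes: int = 40
    trait_prevalence: float = 0.10
    marker_genes: int = 4
    marker_length: int = 300
    dependent_families: int = 3
    dependent_length: int = 150
    dependent_copy_range: tuple[int, int] = (1, 4)
    background_families: int = 150
    background_length_range: tuple[int, int] = (120, 400)
    within_identity: float = 0.75
    window_identity: float = 0.90
    diag_window: tuple[int, int] = (40, 15)
    precursor_length_range: tuple[int, int] = (34, 78)
    cterm_template: str = CTERM_TEMPLATE
    precursors_per_genome: int = 2
    decoys_per_genome: int = 2
    contig_length: int = 3000

    def __post_init__(self) -> None:
        if not 0.0 < self.trait_prevalence < 1.0:
            raise ValueError("trait_prevalence must be in (0,1)")
        if not 0.0 < self.within_identity <= 1.0:
            raise ValueError("identities must be in (0,1]")
        start, length = self.diag_window
        if start + length > self.dependent_length:
            raise ValueError("diagnostic window outside dependent sequence")

    @classmethod
    def sparse(cls, seed: int = 0, **overrides) -> "SynthSpec":
        """~3% trait prevalence preset (134 genomes, 4 trait-positive)."""
        return cls(seed=seed, n_genomes=134, trait_prevalence=0.03, **overrides)


@dataclass(frozen=True)
class PlantedGene:
    contig: str
    strand: str
    start: int  # 1-based inclusive, forward strand, stop codon included
    end: int
    peptide: str
    kind: str  # "precursor" | "decoy"


@dataclass
class TruthLabels:
    """Ground truth of a generated collection."""

    trait: dict[str, bool]
    role: dict[str, str]  # protein -> marker | dependent | background
    family: dict[str, str]  # protein -> family identifier
    diag_windows: dict[str, tuple[int, int]]  # dependent family -> (start, len)
    planted_genes: list[PlantedGene] = field(default_factory=list)

    def members(self, fam: str) -> list[str]:
        return [p for p, f in self.family.items() if f == fam]

    def __post_init__(self) -> None:
        # dependent-family members (and markers) must be confined to
        # trait-positive genomes; checked at construction time.
        for prot, role in self.role.items():
            if role in ("marker", "dependent"):
                genome = prot.split(".")[1]
                if not self.trait[genome]:
                    raise ValueError(f"{role} protein {prot!r} in trait-negative genome")


@dataclass
class SynthBundle:
    spec: SynthSpec
    collection: GenomeCollection
    contigs: dict[str, str]
    truth: TruthLabels
    profile: PhyloProfile


def _fill_template(template: str, rng: np.random.Generator) -> str:
    return "".join(
        STANDARD_AA[rng.integers(0, 20)] if c == "x" else c for c in template
    )


def _reverse_translate(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


def generate_collection(spec: SynthSpec) -> SynthBundle:
    """Generate a genome collection, contigs, truth labels and trait profile.

    Deterministic: the same spec (including seed) yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genomes
    k = round(spec.trait_prevalence * n)
    if k < 1:
        raise ValueError(
            f"spec yields {k} trait-positive genomes "
            f"(prevalence {spec.trait_prevalence} of {n})"
        )
    if k >= n:
        raise ValueError("spec yields no trait-negative genomes")
    genomes = [f"g{i:03d}" for i in range(n)]
    yes_idx = sorted(rng.choice(n, size=k, replace=False))
    trait = {g: (i in set(yes_idx)) for i, g in enumerate(genomes)}
    yes_genomes = [g for g in genomes if trait[g]]

    sequences: dict[str, str] = {}
    index: dict[str, str] = {}
    role: dict[str, str] = {}
    family: dict[str, str] = {}
    diag_windows: dict[str, tuple[int, int]] = {}

    def add(fam: str, genome: str, copy: int, seq: str, r: str) -> None:
        pid = f"{fam}.{genome}.{copy}"
        sequences[pid] = seq
        index[pid] = genome
        role[pid] = r
        family[pid] = fam

    # marker cluster: one single-copy family per cluster gene, YES genomes only
    for m in range(spec.marker_genes):
        fam = f"mkr{m}"
        anc = random_protein(spec.marker_length, rng)
        for g in yes_genomes:
            add(fam, g, 0, mutate_sequence(anc, spec.within_identity, rng), "marker")

    # dependent/sister pairs sharing an ancestor, differing in the diagnostic window
    w_start, w_len = spec.diag_window
    for d in range(spec.dependent_families):
        dep_fam, sis_fam = f"dep{d}", f"sis{d}"
        anc = random_protein(spec.dependent_length, rng)
        motif_true = random_protein(w_len, rng)
        motif_false = "".join(  # differs from motif_true at every position
            STANDARD_AA[(_AA_INDEX[c] + 1 + rng.integers(0, 19)) % 20]
            for c in motif_true
        )
        diag_windows[dep_fam] = (w_start, w_len)
        lo, hi = spec.dependent_copy_range
        for g in yes_genomes:
            for c in range(rng.integers(lo, hi + 1)):
                seq = mutate_sequence(anc, spec.within_identity, rng)
                win = mutate_sequence(motif_true, spec.window_identity, rng)
                add(dep_fam, g, c, seq[:w_start] + win + seq[w_start + w_len :], "dependent")
        for g in genomes:
            seq = mutate_sequence(anc, spec.within_identity, rng)
            win = mutate_sequence(motif_false, spec.window_identity, rng)
            add(sis_fam, g, 0, seq[:w_start] + win + seq[w_start + w_len :], "background")

    # background families: one copy in every genome
    lo_len, hi_len = spec.background_length_range
    for b in range(spec.background_families):
        fam = f"bg{b:03d}"
        anc = random_protein(int(rng.integers(lo_len, hi_len + 1)), rng)
        for g in genomes:
            add(fam, g, 0, mutate_sequence(anc, spec.within_identity, rng), "background")

    truth = TruthLabels(trait, role, family, diag_windows)

    # contigs with planted precursor genes (YES genomes) and decoys (all)
    contigs: dict[str, str] = {}
    motif = MotifSpec(
        pattern="".join("x" if c == "x" else c for c in spec.cterm_template[-8:]),
        max_distance=0,
    )
    for g in genomes:
        cid = f"{g}_contig"
        genes: list[tuple[str, str]] = []  # (peptide, kind)
        if trait[g]:
            for _ in range(spec.precursors_per_genome):
                genes.append((_precursor_peptide(spec, rng), "precursor"))
        for _ in range(spec.decoys_per_genome):
            genes.append((_decoy_peptide(spec, rng, motif), "decoy"))
        contigs[cid] = _assemble_contig(cid, genes, spec, rng, truth)
    collection = GenomeCollection(genomes, index, sequences)
    profile = PhyloProfile(trait)
    return SynthBundle(spec, collection, contigs, truth, profile)


def _precursor_peptide(spec: SynthSpec, rng: np.random.Generator) -> str:
    cterm = _fill_template(spec.cterm_template, rng)
    lo, hi = spec.precursor_length_range
    total = int(rng.integers(lo, hi + 1))
    nterm_len = max(1, total - len(cterm))
    return "M" + random_protein(nterm_len - 1, rng) + cterm


def _decoy_peptide(
    spec: SynthSpec, rng: np.random.Generator, motif: MotifSpec
) -> str:
    lo, hi = spec.precursor_length_range
    total = int(rng.integers(lo, hi + 1))
    while True:
        shuffled = "".join(
            np.array(list(_fill_template(spec.cterm_template, rng)))[
                rng.permutation(len(spec.cterm_template))
            ]
        )
        peptide = "M" + random_protein(max(1, total - len(shuffled)) - 1, rng) + shuffled
        if not motif.matches(peptide):
            return peptide


def _assemble_contig(
    cid: str,
    genes: Sequence[tuple[str, str]],
    spec: SynthSpec,
    rng: np.random.Generator,
    truth: TruthLabels,
) -> str:
    """Interleave random DNA with gene cassettes; record planted coordinates.

    Each cassette is an in-frame TAA (so the maximal ORF starts at the
    planted ATG) followed by the CDS (ATG .. TAA), inserted forward or
    reverse-complemented.
    """
    parts: list[str] = []
    pos = 0
    for peptide, kind in genes:
        gap = int(rng.integers(100, 300))
        parts.append(random_dna(gap, rng))
        pos += gap
        cds = _reverse_translate(peptide) + "TAA"
        cassette = "TAA" + cds
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            parts.append(cassette)
            start, end = pos + 3 + 1, pos + len(cassette)
        else:
            parts.append(str(Seq(cassette).reverse_complement()))
            start, end = pos + 1, pos + len(cds)
        truth.planted_genes.append(PlantedGene(cid, strand, start, end, peptide, kind))
        pos += len(cassette)
    tail = max(0, spec.contig_length - pos)
    parts.append(random_dna(max(tail, 100), rng))
    return "".join(parts)


# ---------------------------------------------------------------------------
# model-based hit tables (stand-in for precomputed all-vs-all search)
# ---------------------------------------------------------------------------


def _hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("family members must share their ancestor's length")
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return float((arr_a == arr_b).mean())


def _partner(fam: str) -> str | None:
    if fam.startswith("dep"):
        return "sis" + fam[3:]
    if fam.startswith("sis"):
        return "dep" + fam[3:]
    return None


def emit_hit_tables(
    bundle: SynthBundle,
    path: str | Path,
    seed: int = 0,
    noise_sd: float = 3.0,
    queries: Sequence[str] | None = None,
) -> None:
    """Write a 12-column tabular hit file for the collection.

    Each query's subjects are its family members (plus the paired
    dependent/sister clade, which shares the family ancestor); scores are
    ``2 * length * identity`` plus Gaussian noise, so within-family scores
    exceed cross-clade scores on average and, at zero noise, every hit list
    is exactly its family ordered by identity. The self-hit always tops its
    list.
    """
    rng = np.random.default_rng(seed)
    seqs = bundle.collection.sequences
    truth = bundle.truth
    members: dict[str, list[str]] = {}
    for pid, fam in truth.family.items():
        members.setdefault(fam, []).append(pid)
    if queries is None:
        queries = list(seqs)
    with open(path, "w") as fh:
        for q in queries:
            fam = truth.family[q]
            subjects = list(members[fam])
            partner = _partner(fam)
            if partner is not None:
                subjects += members.get(partner, [])
            length = len(seqs[q])
            rows = []
            for s in subjects:
                ident = _hamming_identity(seqs[q], seqs[s])
                if s == q:
                    score = 2.0 * length + 10.0
                else:
                    score = 2.0 * length * ident + (
                        rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    )
                rows.append((s, ident, score))
            rows.sort(key=lambda r: -r[2])
            for s, ident, score in rows:
                mism = round((1 - ident) * length)
                fh.write(
                    f"{q}\t{s}\t{100 * ident:.2f}\t{length}\t{mism}\t0"
                    f"\t1\t{length}\t1\t{length}\t1e-10\t{score:.3f}\n"
                )


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/TSV artifacts of a generated collection to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.faa",
        "genome_map": outdir / "genome_map.tsv",
        "trait": outdir / "trait.tsv",
        "contigs": outdir / "contigs.fna",
        "truth": outdir / "truth.tsv",
    }
    write_fasta_collection(bundle.collection, paths["proteins"], paths["genome_map"])
    write_profile(bundle.profile, paths["trait"])
    with open(paths["contigs"], "w") as fh:
        for cid, seq in bundle.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write(f"# seed: {bundle.spec.seed}\n")
        fh.write("record\tkind\tdetail\n")
        for pid, r in bundle.truth.role.items():
            fh.write(f"{pid}\t{r}\t{bundle.truth.family[pid]}\n")
        for gene in bundle.truth.planted_genes:
            fh.write(
                f"{gene.contig}:{gene.start}-{gene.end}({gene.strand})\t{gene.kind}"
                f"\t{gene.peptide}\n"
            )
    return paths
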