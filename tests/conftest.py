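from __future__ import annotations

import pytest

from phyloprofiler.core import GenomeCollection, Hit, HitList, PhyloProfile
from phyloprofiler.synth import SynthSpec, generate_collection


TINY_SPEC = SynthSpec(
    seed=11,
    n_genomes=10,
    trait_prevalence=0.3,
    marker_genes=2,
    marker_length=80,
    dependent_families=1,
    dependent_length=60,
    diag_window=(20, 12),
    background_families=8,
    background_length_range=(60, 120),
    contig_length=1200,
)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small 10-genome collection for fast structural tests."""
    return generate_collection(TINY_SPEC)


@pytest.fixture(scope="session")
def default_bundle():
    """Full default-scale collection (40 genomes) for recovery tests."""
    return generate_collection(SynthSpec(seed=1))


def make_hitlist(query: str, rows: list[tuple[str, str, float]]) -> HitList:
    """rows: (subject, subject_genome, score) in the intended input order."""
    hits = [Hit(query, s, g, sc, rank=1) for s, g, sc in rows]
    return HitList.from_unsorted(query, hits)


def make_profile(yes: list[str], no: list[str]) -> PhyloProfile:
    labels = {g: True for g in yes}
    labels.update({g: False for g in no})
    return PhyloProfile(labels)


def make_collection(assignments: dict[str, tuple[str, str]]) -> GenomeCollection:
    """assignments: protein -> (genome, sequence)."""
    genomes: list[str] = []
    for genome, _ in assignments.values():
        if genome not in genomes:
            genomes.append(genome)
    return GenomeCollection(
        genomes=genomes,
        protein_index={p: g for p, (g, _) in assignments.items()},
        sequences={p: s for p, (_, s) in assignments.items()},
    )
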