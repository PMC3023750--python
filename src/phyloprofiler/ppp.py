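"""Partial Phylogenetic Profiling (PPP).

Each protein is scored independently by walking its ranked similarity hit
list and evaluating every admissible score cutoff. At a cutoff the prefix of
hits above it covers ``n`` distinct genomes, ``y`` of them trait-positive;
under the null model the trait-positive count is Binomial(n, p) with p the
trait prevalence, and the reported score is

    score = log10 P(X >= y),  X ~ Binomial(n, p)

The cutoff minimizing this score (most negative = most enriched) wins;
equal scores resolve to the shallower cutoff, which reports the most
parsimonious candidate family. Ranking all proteins of a genome by their
optimal scores surfaces the families whose presence/absence pattern best
matches the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import GenomeCollection, HitList, PhyloProfile, PPPResult

_LN10 = math.log(10.0)


def _check_ynp(y: int, n: int, p: float) -> None:
    if not 0 <= y <= n:
        raise ValueError(f"require 0 <= y <= n, got y={y}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {p}")


def log10_binom_point(y: int, n: int, p: float) -> float:
    """log10 P(X = y) for X ~ Binomial(n, p), via log-gamma."""
    _check_ynp(y, n, p)
    ln = (
        gammaln(n + 1)
        - gammaln(y + 1)
        - gammaln(n - y + 1)
        + y * math.log(p)
        + (n - y) * math.log1p(-p)
    )
    return float(ln) / _LN10


def log10_binom_tail(y: int, n: int, p: float) -> float:
    """log10 of the binomial upper tail P(X >= y), X ~ Binomial(n, p).

    Computed in log space: log-gamma for the combinatorial terms and a
    log-sum-exp over the tail. Two exact shortcuts: y = 0 gives 0 (the tail
    is the whole distribution) and y = n gives n * log10(p) (the single
    all-successes term).
    """
    _check_ynp(y, n, p)
    if y == 0:
        return 0.0
    if y == n:
        return n * math.log10(p)
    ks = np.arange(y, n + 1)
    ln_terms = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * math.log(p)
        + (n - ks) * math.log1p(-p)
    )
    return min(0.0, float(logsumexp(ln_terms)) / _LN10)


@dataclass(frozen=True)
class PPPConfig:
    """Cutoff-search options.

    max_depth: stop traversing the hit list after this many hits (tie blocks
        are never split, so the last block may overshoot); None = full list.
    include_self_genome: count hits from the query's own genome (the query's
        self-hit and its genome belong to the candidate family by default).
    """

    max_depth: int | None = None
    include_self_genome: bool = True

    def __post_init__(self) -> None:
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


DEFAULT_CONFIG = PPPConfig()


def evaluate_prefixes(
    hitlist: HitList,
    profile: PhyloProfile,
    config: PPPConfig = DEFAULT_CONFIG,
    prevalence: float | None = None,
    query_genome: str | None = None,
) -> PPPResult:
    """Find the best score cutoff for one hit list.

    Walks cutoffs in order of decreasing score, never splitting an
    equal-score tie block, accumulating distinct genomes (``n``), distinct
    trait-positive genomes (``y``) and traversed hits (``depth``). Returns
    the prefix minimizing ``log10_binom_tail(y, n, p)``; the empty prefix
    (score 0) is a legal outcome and wins all score ties at lesser depth.

    ``prevalence`` overrides the profile's K/N (used to calibrate against
    published tables whose exact profile is unavailable).
    """
    p = profile.prevalence if prevalence is None else prevalence
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {p}")

    best_score, best = 0.0, (0, 0, 0)
    genomes_seen: set[str] = set()
    yes_seen: set[str] = set()
    depth = 0
    for block in hitlist.tie_blocks():
        for hit in block:
            if (
                not config.include_self_genome
                and query_genome is not None
                and hit.subject_genome == query_genome
            ):
                continue
            depth += 1
            genomes_seen.add(hit.subject_genome)
            try:
                if profile.is_yes(hit.subject_genome):
                    yes_seen.add(hit.subject_genome)
            except KeyError:
                raise ValueError(
                    f"genome {hit.subject_genome!r} of hit {hit.subject!r} "
                    "is not covered by the profile"
                ) from None
        score = log10_binom_tail(len(yes_seen), len(genomes_seen), p)
        if score < best_score:
            best_score = score
            best = (len(yes_seen), len(genomes_seen), depth)
        if config.max_depth is not None and depth >= config.max_depth:
            break
    y, n, d = best
    return PPPResult(hitlist.query, y, n, d, best_score)


def profile_from_marker(
    collection: GenomeCollection, members: set[str] | frozenset[str]
) -> PhyloProfile:
    """Derive the query profile from a marker family's membership.

    A genome is labelled YES iff it encodes at least one member protein.
    """
    if not members:
        raise ValueError("marker membership is empty")
    unknown = members - set(collection.protein_index)
    if unknown:
        raise ValueError(f"marker members not in collection: {sorted(unknown)}")
    yes_genomes = {collection.protein_index[m] for m in members}
    labels = {g: g in yes_genomes for g in collection.genomes}
    return PhyloProfile(labels)  # raises if K == 0 or K == N


def ppp_rank_genome(
    genome: str,
    hitlists: dict[str, HitList],
    profile: PhyloProfile,
    collection: GenomeCollection,
    config: PPPConfig = DEFAULT_CONFIG,
) -> list[PPPResult]:
    """Score every protein of one genome and rank by ascending score.

    Proteins absent from ``hitlists`` get an empty hit list (score 0).
    Ties sort by protein identifier, so the table is independent of input
    protein order.
    """
    results = []
    for prot in collection.proteins_of(genome):
        hl = hitlists.get(prot, HitList(prot, []))
        results.append(
            evaluate_prefixes(hl, profile, config, query_genome=genome)
        )
    results.sort(key=lambda r: (r.score, r.query))
    return results
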