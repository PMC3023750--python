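"""SIMBAL: subsequence-window trait-association mapping.

A protein family is split into TRUE and FALSE partitions according to a
genome-level trait profile (not any property of the proteins themselves),
each partition is thinned so no kept pair exceeds 80% identity, and every
subsequence window of a probe protein is scored against the combined
training set with the same optimal-cutoff binomial statistic as full-length
profiling — except that each training *sequence* is its own profile unit and
the prevalence is the TRUE fraction of the training set. Scores are
displayed as -log10 of the tail probability (positive, hotter = larger), on
a triangular (window center x window length) grid whose apex is the single
full-length window. Plumes rising from short windows mark subsequences whose
similarity neighbourhood is dominated by trait-positive sequences.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .align import DEFAULT_PARAMS, ScoringParams, global_align, local_align_score, pairwise_identity
from .core import GenomeCollection, Hit, HitList, PhyloProfile
from .ppp import PPPConfig, evaluate_prefixes


@dataclass
class TrainingSet:
    """Trait-partitioned, dereplicated training sequences."""

    true_seqs: dict[str, str]
    false_seqs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.true_seqs or not self.false_seqs:
            raise ValueError("both training partitions must be non-empty")
        overlap = set(self.true_seqs) & set(self.false_seqs)
        if overlap:
            raise ValueError(f"sequences in both partitions: {sorted(overlap)}")

    @property
    def prevalence(self) -> float:
        """TRUE fraction p_t of the training set."""
        return len(self.true_seqs) / (len(self.true_seqs) + len(self.false_seqs))

    def labels(self) -> dict[str, bool]:
        out = {sid: True for sid in self.true_seqs}
        out.update({sid: False for sid in self.false_seqs})
        return out

    def items(self):
        yield from self.true_seqs.items()
        yield from self.false_seqs.items()


@dataclass(frozen=True)
class SimbalWindow:
    start: int  # 0-based
    length: int
    score: float  # -log10 tail, >= 0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("window score must be >= 0")

    @property
    def center(self) -> float:
        return self.start + self.length / 2

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass
class SimbalGrid:
    """Triangular window-score surface for one probe."""

    probe: str
    probe_length: int
    min_len: int
    len_step: int
    pos_step: int
    windows: list[SimbalWindow] = field(default_factory=list)

    @property
    def apex(self) -> SimbalWindow:
        full = [w for w in self.windows if w.length == self.probe_length]
        if len(full) != 1:
            raise ValueError(f"expected exactly 1 full-length window, got {len(full)}")
        return full[0]

    def best(self) -> SimbalWindow:
        """Global maximum; ties go to the earliest enumerated window."""
        return max(self.windows, key=lambda w: w.score)


@dataclass(frozen=True)
class SimbalConfig:
    min_len: int = 8
    len_step: int = 4
    pos_step: int = 2
    params: ScoringParams = DEFAULT_PARAMS
    min_length_frac: float = 0.5  # fragment filter, fraction of partition median
    max_identity: float = 0.80


DEFAULT_SIMBAL = SimbalConfig()


def dereplicate(
    sequences: Mapping[str, str], max_identity: float = 0.80
) -> dict[str, str]:
    """Greedy thinning in input order: keep a sequence iff its global-alignment
    identity to every already-kept sequence is <= ``max_identity`` (pairs
    *greater* than the threshold are redundant)."""
    kept: dict[str, str] = {}
    for sid, seq in sequences.items():
        if all(pairwise_identity(seq, k) <= max_identity for k in kept.values()):
            kept[sid] = seq
    return kept


def build_training(
    family: Mapping[str, str],
    collection: GenomeCollection,
    profile: PhyloProfile,
    config: SimbalConfig = DEFAULT_SIMBAL,
) -> TrainingSet:
    """Partition a family by its genomes' trait labels, drop fragments, thin.

    Fragment filter: sequences shorter than ``min_length_frac`` x the
    partition's median length are removed before dereplication.
    """
    parts: dict[bool, dict[str, str]] = {True: {}, False: {}}
    for sid, seq in family.items():
        try:
            genome = collection.protein_index[sid]
        except KeyError:
            raise ValueError(f"family sequence {sid!r} not in collection") from None
        parts[profile.is_yes(genome)][sid] = seq

    cleaned: dict[bool, dict[str, str]] = {}
    for label, seqs in parts.items():
        if seqs:
            median = statistics.median(len(s) for s in seqs.values())
            seqs = {
                sid: s
                for sid, s in seqs.items()
                if len(s) >= config.min_length_frac * median
            }
        if not seqs:
            raise ValueError(
                f"{'TRUE' if label else 'FALSE'} partition empty after filtering"
            )
        cleaned[label] = dereplicate(seqs, config.max_identity)
    return TrainingSet(true_seqs=cleaned[True], false_seqs=cleaned[False])


def enumerate_windows(
    probe_length: int,
    min_len: int = 8,
    len_step: int = 4,
    pos_step: int = 2,
) -> list[tuple[int, int]]:
    """All (start, length) windows: lengths min_len, min_len+step, ... plus the
    full length (the apex), starts stepped by pos_step."""
    if probe_length < min_len:
        raise ValueError(f"probe length {probe_length} < min window {min_len}")
    lengths = list(range(min_len, probe_length, len_step))
    lengths.append(probe_length)
    out = []
    for length in lengths:
        for start in range(0, probe_length - length + 1, pos_step):
            out.append((start, length))
    return out


def score_window(
    window_seq: str,
    training: TrainingSet,
    params: ScoringParams = DEFAULT_PARAMS,
    ppp_config: PPPConfig | None = None,
) -> float:
    """Optimal-cutoff enrichment score of one subsequence (>= 0).

    Every training sequence is ranked by its local-alignment score to the
    window; the cutoff walk is identical to full-length profiling with each
    sequence acting as its own single-member genome and p = the training
    TRUE fraction. Returns -log10 of the best tail probability; a window
    whose hits never enrich for TRUE sequences scores 0.
    """
    hits = []
    for sid, seq in training.items():
        s = local_align_score(window_seq, seq, params)
        if s > params.score_floor:
            hits.append(Hit("window", sid, sid, s, rank=1))
    hitlist = HitList.from_unsorted("window", hits)
    profile = PhyloProfile(training.labels())
    result = evaluate_prefixes(
        hitlist, profile, ppp_config or PPPConfig(), prevalence=training.prevalence
    )
    return -result.score


def simbal_heatmap(
    probe_id: str,
    probe_seq: str,
    training: TrainingSet,
    config: SimbalConfig = DEFAULT_SIMBAL,
) -> SimbalGrid:
    """Score every enumerated window of the probe against the training set."""
    grid = SimbalGrid(
        probe=probe_id,
        probe_length=len(probe_seq),
        min_len=config.min_len,
        len_step=config.len_step,
        pos_step=config.pos_step,
    )
    for start, length in enumerate_windows(
        len(probe_seq), config.min_len, config.len_step, config.pos_step
    ):
        s = score_window(probe_seq[start : start + length], training, config.params)
        grid.windows.append(SimbalWindow(start, length, s))
    return grid


@dataclass(frozen=True)
class HomologInterval:
    """Probe window mapped onto a homolog via global alignment (1-based, inclusive)."""

    start: int
    end: int
    gapped_positions: int
    empty: bool = False


def map_window_to_homolog(
    window: tuple[int, int] | SimbalWindow,
    probe_seq: str,
    homolog_seq: str,
) -> HomologInterval:
    """Locate the homolog residues aligned to a probe window.

    Globally aligns probe to homolog and returns the 1-based inclusive
    homolog interval covered by the window's columns; window positions
    opposite a homolog gap are counted in ``gapped_positions``. A window
    falling entirely within a gap yields an empty, flagged interval.
    """
    if isinstance(window, SimbalWindow):
        start, length = window.start, window.length
    else:
        start, length = window
    if start < 0 or start + length > len(probe_seq):
        raise ValueError("window outside probe")
    alignment = global_align(probe_seq, homolog_seq)
    indices = alignment.indices  # 2 x n_columns, -1 at gaps
    probe_cols = [
        c for c in range(indices.shape[1]) if start <= indices[0, c] < start + length
    ]
    homolog_pos = [int(indices[1, c]) for c in probe_cols if indices[1, c] >= 0]
    gapped = sum(1 for c in probe_cols if indices[1, c] < 0)
    if not homolog_pos:
        return HomologInterval(0, 0, gapped, empty=True)
    return HomologInterval(min(homolog_pos) + 1, max(homolog_pos) + 1, gapped)


def write_grid_tsv(
    grid: SimbalGrid, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# probe: {grid.probe}\n")
        fh.write(f"# probe_length: {grid.probe_length}\n")
        fh.write(
            f"# grid: min_len={grid.min_len} len_step={grid.len_step} "
            f"pos_step={grid.pos_step}\n"
        )
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("start\tlength\tcenter\tscore\n")
        for w in grid.windows:
            fh.write(f"{w.start}\t{w.length}\t{w.center:.1f}\t{w.score:.6f}\n")


def plot_grid(grid: SimbalGrid, path: str | Path) -> None:
    """Render the triangular heat map (optional artifact; analysis uses the TSV)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    xs = [w.center for w in grid.windows]
    ys = [w.length for w in grid.windows]
    cs = [w.score for w in grid.windows]
    sc = ax.scatter(xs, ys, c=cs, cmap="jet", s=12, marker="s")
    fig.colorbar(sc, ax=ax, label="-log10 tail probability")
    ax.set_xlabel("window center (residue)")
    ax.set_ylabel("window length")
    ax.set_title(grid.probe)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
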