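import math

import numpy as np
import pytest

from phyloprofiler.align import DEFAULT_PARAMS
from phyloprofiler.core import STANDARD_AA, PhyloProfile
from phyloprofiler.ppp import evaluate_prefixes
from phyloprofiler.simbal import (
    SimbalConfig,
    TrainingSet,
    build_training,
    dereplicate,
    enumerate_windows,
    map_window_to_homolog,
    score_window,
    simbal_heatmap,
    write_grid_tsv,
)
from phyloprofiler.synth import mutate_sequence, random_protein

from conftest import make_collection, make_profile


def _random_seqs(rng, n, length=60):
    return {f"s{i}": random_protein(length, rng) for i in range(n)}


class TestEnumerateWindows:
    def test_counts_for_small_probe(self):
        wins = enumerate_windows(10, min_len=8, len_step=1, pos_step=1)
        # lengths 8 (3 starts), 9 (2), 10 (1)
        assert len(wins) == 6
        assert (0, 10) in wins

    def test_probe_at_minimum_length_gives_apex_only(self):
        assert enumerate_windows(8, min_len=8) == [(0, 8)]

    def test_probe_shorter_than_minimum_is_error(self):
        with pytest.raises(ValueError):
            enumerate_windows(7, min_len=8)

    @pytest.mark.parametrize("L,min_len,len_step,pos_step", [
        (50, 8, 4, 2), (33, 10, 3, 5), (100, 8, 12, 7),
    ])
    def test_count_matches_closed_form(self, L, min_len, len_step, pos_step):
        lengths = list(range(min_len, L, len_step)) + [L]
        expected = sum((L - l) // pos_step + 1 for l in lengths)
        wins = enumerate_windows(L, min_len, len_step, pos_step)
        assert len(wins) == expected
        assert len(set(wins)) == len(wins)
        assert sum(1 for _, l in wins if l == L) == 1


class TestDereplicate:
    def test_identical_pair_keeps_first(self):
        seq = "MKVLADHEAGWGHEE"
        kept = dereplicate({"a": seq, "b": seq})
        assert list(kept) == ["a"]

    def test_distant_pair_both_kept(self):
        rng = np.random.default_rng(0)
        a = random_protein(100, rng)
        b = mutate_sequence(a, 0.5, rng)
        kept = dereplicate({"a": a, "b": b})
        assert set(kept) == {"a", "b"}

    def test_three_tight_groups_collapse_to_three(self):
        from phyloprofiler.align import pairwise_identity

        rng = np.random.default_rng(1)
        ancestors = [random_protein(120, rng) for _ in range(3)]
        seqs = {}
        for gi, anc in enumerate(ancestors):
            for m in range(10):
                seqs[f"grp{gi}_{m}"] = mutate_sequence(anc, 0.95, rng)
        # verify the construction: within-group identities exceed the
        # threshold, between-group identities fall below it
        assert pairwise_identity(seqs["grp0_0"], seqs["grp0_1"]) > 0.80
        assert pairwise_identity(seqs["grp0_0"], seqs["grp1_0"]) < 0.80
        kept = dereplicate(seqs, max_identity=0.80)
        assert len(kept) == 3
        assert {k.split("_")[0] for k in kept} == {"grp0", "grp1", "grp2"}


class TestBuildTraining:
    def _collection(self, seqs, trait):
        coll = make_collection(
            {sid: (f"g{sid}", seq) for sid, seq in seqs.items()}
        )
        prof = make_profile(
            yes=[f"g{s}" for s in trait], no=[f"g{s}" for s in seqs if s not in trait]
        )
        return coll, prof

    def test_partition_sizes_and_prevalence(self):
        rng = np.random.default_rng(2)
        seqs = _random_seqs(rng, 6)
        coll, prof = self._collection(seqs, {"s0", "s1"})
        tr = build_training(seqs, coll, prof)
        assert set(tr.true_seqs) == {"s0", "s1"}
        assert len(tr.false_seqs) == 4
        assert tr.prevalence == pytest.approx(1 / 3)

    def test_fragment_removed_by_length_filter(self):
        rng = np.random.default_rng(3)
        seqs = _random_seqs(rng, 6, length=300)
        seqs["frag"] = seqs["s0"][:10]
        coll, prof = self._collection(seqs, {"s0", "s1"})
        tr = build_training(seqs, coll, prof)
        assert "frag" not in tr.false_seqs and "frag" not in tr.true_seqs

    def test_empty_partition_is_error(self):
        rng = np.random.default_rng(4)
        seqs = _random_seqs(rng, 3)
        coll = make_collection({s: (f"g{s}", q) for s, q in seqs.items()})
        prof = make_profile(yes=["gs0"], no=["gs1", "gs2", "gx"])
        only_false = {k: v for k, v in seqs.items() if k != "s0"}
        with pytest.raises(ValueError, match="TRUE partition empty"):
            build_training(only_false, coll, prof)


def _training(rng, n_true=6, n_false=12, length=50):
    anc_t = random_protein(length, rng)
    true = {f"t{i}": mutate_sequence(anc_t, 0.9, rng) for i in range(n_true)}
    false = {f"f{i}": random_protein(length, rng) for i in range(n_false)}
    return TrainingSet(true_seqs=true, false_seqs=false)


# BLOSUM62 scores W negatively against every residue in this alphabet, so a
# poly-W sequence has no positive-scoring local alignment to one built from it
_NO_W_PARTNERS = "ACDEGHIKLMNPQRST"


def _protein_without_w_partners(length, rng):
    return "".join(np.array(list(_NO_W_PARTNERS))[rng.integers(0, len(_NO_W_PARTNERS), size=length)])


class TestScoreWindow:
    def test_window_hitting_only_false_at_every_cutoff_scores_zero(self):
        rng = np.random.default_rng(5)
        false_anc = _protein_without_w_partners(40, rng)
        training = TrainingSet(
            true_seqs={"t0": "W" * 40},
            false_seqs={f"f{i}": mutate_sequence(false_anc, 1.0, rng) for i in range(5)},
        )
        # the TRUE sequence never reaches a positive score, so y=0 at all depths
        assert score_window(false_anc, training) == 0.0

    def test_perfect_true_prefix_reaches_identity_bound(self):
        rng = np.random.default_rng(6)
        training = _training(rng)
        window = training.true_seqs["t0"]
        t, p_t = len(training.true_seqs), training.prevalence
        score = score_window(window, training)
        assert score >= -t * math.log10(p_t) - 1e-9

    def test_unreachable_true_partition_forces_zero_everywhere(self):
        # when no TRUE sequence ever enters a hit list, every window of the
        # probe must score exactly 0 (no FALSE-only prefix can enrich)
        rng = np.random.default_rng(7)
        probe = _protein_without_w_partners(30, rng)
        training = TrainingSet(
            true_seqs={"t0": "W" * 30},
            false_seqs={f"f{i}": _protein_without_w_partners(30, rng) for i in range(8)},
        )
        grid = simbal_heatmap("probe", probe, training, SimbalConfig(min_len=8, len_step=8, pos_step=8))
        assert all(w.score == 0.0 for w in grid.windows)


class TestApexConsistency:
    def test_apex_equals_full_length_profile_score(self):
        rng = np.random.default_rng(8)
        training = _training(rng)
        probe = training.true_seqs["t0"]
        apex = score_window(probe, training)
        # independent route: every training sequence becomes a single-member
        # genome and the full-length probe is profiled against it
        from phyloprofiler.align import rank_hits

        coll = make_collection(
            {sid: (sid, seq) for sid, seq in training.items()}
        )
        prof = PhyloProfile(training.labels())
        hl = rank_hits("probe", probe, coll)
        res = evaluate_prefixes(hl, prof, prevalence=training.prevalence)
        assert apex == -res.score


class TestHeatmap:
    def test_grid_is_triangular_with_single_apex(self):
        rng = np.random.default_rng(9)
        training = _training(rng, length=40)
        probe = training.true_seqs["t0"]
        grid = simbal_heatmap("p", probe, training, SimbalConfig(min_len=8, len_step=8, pos_step=4))
        full = [w for w in grid.windows if w.length == len(probe)]
        assert len(full) == 1
        assert grid.apex == full[0]
        per_length = {}
        for w in grid.windows:
            per_length[w.length] = per_length.get(w.length, 0) + 1
        lengths = sorted(per_length)
        assert all(per_length[a] >= per_length[b] for a, b in zip(lengths, lengths[1:]))
        assert all(w.score >= 0 for w in grid.windows)

    def test_heatmap_is_deterministic(self):
        rng = np.random.default_rng(10)
        training = _training(rng, length=30)
        probe = training.true_seqs["t1"]
        cfg = SimbalConfig(min_len=8, len_step=8, pos_step=6)
        g1 = simbal_heatmap("p", probe, training, cfg)
        g2 = simbal_heatmap("p", probe, training, cfg)
        assert g1.windows == g2.windows

    def test_grid_tsv_and_plot(self, tmp_path):
        rng = np.random.default_rng(11)
        training = _training(rng, length=30)
        probe = training.true_seqs["t0"]
        grid = simbal_heatmap("p", probe, training, SimbalConfig(min_len=8, len_step=8, pos_step=10))
        write_grid_tsv(grid, tmp_path / "g.tsv")
        lines = (tmp_path / "g.tsv").read_text().splitlines()
        assert "start\tlength\tcenter\tscore" in lines
        n_data = sum(1 for l in lines if l and not l.startswith(("#", "start")))
        assert n_data == len(grid.windows)
        from phyloprofiler.simbal import plot_grid

        plot_grid(grid, tmp_path / "g.png")
        assert (tmp_path / "g.png").stat().st_size > 0


class TestMapWindowToHomolog:
    def test_identity_mapping_shifts_to_one_based(self):
        rng = np.random.default_rng(12)
        probe = random_protein(60, rng)
        iv = map_window_to_homolog((10, 8), probe, probe)
        assert (iv.start, iv.end, iv.gapped_positions) == (11, 18, 0)

    def test_nterminal_extension_shifts_interval(self):
        rng = np.random.default_rng(13)
        probe = random_protein(60, rng)
        homolog = "MKVLA" + probe
        iv = map_window_to_homolog((10, 8), probe, homolog)
        assert (iv.start, iv.end) == (16, 23)

    def test_internal_deletion_matches_hand_alignment(self):
        rng = np.random.default_rng(14)
        probe = random_protein(60, rng)
        homolog = probe[:20] + probe[30:]  # residues 21..30 deleted
        # window inside the deletion maps to nothing
        iv = map_window_to_homolog((22, 6), probe, homolog)
        assert iv.empty and iv.gapped_positions == 6
        # window spanning the deletion boundary: only flanks align
        iv2 = map_window_to_homolog((15, 20), probe, homolog)
        assert (iv2.start, iv2.end) == (16, 25)
        assert iv2.gapped_positions == 10

    def test_window_outside_probe_is_error(self):
        with pytest.raises(ValueError):
            map_window_to_homolog((5, 10), "MKVLAD", "MKVLAD")
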