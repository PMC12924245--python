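"""CRISPR array handling, spacer sharing/orientation, matching and FDR."""

import json
from collections import Counter

import numpy as np
import pytest

from phagewatch import crispr
from phagewatch.boundary import revcomp
from phagewatch.crispr import CrisprArray, Spacer
from phagewatch.model import GenomeRecord, PipelineConfig
from phagewatch.synthetic import (
    build_cassette,
    make_crispr_fixture,
    make_host_genome,
    plant_crispr_array,
    random_dna,
)


def simple_array(seqs, array_id="arr", genome="g"):
    return CrisprArray(
        array_id=array_id, genome_id=genome, interval=None,
        repeat_consensus="ACGT" * 8,
        spacers=[Spacer(s, i, array_id) for i, s in enumerate(seqs)],
        cas_type="I-E")


@pytest.fixture
def phage_pair():
    a = build_cassette(seed=31, phage_id="pA")
    b = build_cassette(seed=32, phage_id="pB")
    return [("pA", a.seq), ("pB", b.seq)]


class TestIngestion:
    def test_normalized_tsv_roundtrip(self, tmp_path):
        rows = ["array_id\tgenome_id\tcas_type\tindex\tspacer_seq"]
        spacers = [random_dna(32, np.random.default_rng(i)) for i in range(5)]
        for i, s in enumerate(spacers):
            rows.append(f"Bath_TypeIC\tBath\tI-C\t{i}\t{s}")
        p = tmp_path / "arrays.tsv"
        p.write_text("\n".join(rows) + "\n")
        arrays = crispr.ingest_crispr_arrays(p, "normalized_tsv")
        assert len(arrays) == 1
        assert [sp.seq for sp in arrays[0].spacers] == spacers
        assert arrays[0].cas_type == "I-C"

    def test_ccf_json_spacer_count_and_orientation(self, tmp_path):
        rng = np.random.default_rng(41)
        spacers = [random_dna(30, rng) for _ in range(69)]
        doc = {"Sequences": [{
            "Id": "Bath",
            "Crisprs": [{
                "Name": "Bath_1", "Start": 100, "End": 5000,
                "DR_Consensus": "ACGT" * 8, "CasType": "I-E",
                "Potential_Orientation": "+",
                "Regions": ([{"Type": "DR", "Sequence": "ACGT" * 8}]
                            + [x for s in spacers
                               for x in ({"Type": "Spacer", "Sequence": s},
                                         {"Type": "DR", "Sequence": "ACGT" * 8})]),
            }, {
                "Name": "Bath_2",
                "Potential_Orientation": "-",
                "Regions": [{"Type": "Spacer", "Sequence": s} for s in spacers[:4]],
            }, {
                "Name": "Bath_empty",
                "Regions": [{"Type": "DR", "Sequence": "ACGT" * 8}],
            }],
        }]}
        p = tmp_path / "ccf.json"
        p.write_text(json.dumps(doc))
        arrays = crispr.ingest_crispr_arrays(p, "crisprcasfinder_json")
        assert len(arrays) == 2  # empty array skipped
        assert len(arrays[0].spacers) == 69
        # reverse orientation: spacers reverse-complemented and reversed
        assert [sp.seq for sp in arrays[1].spacers] == \
            [revcomp(s) for s in reversed(spacers[:4])]

    def test_no_cas_genes_tagged_none(self, tmp_path):
        p = tmp_path / "arrays.tsv"
        p.write_text("array_id\tgenome_id\tcas_type\tindex\tspacer_seq\n"
                     f"Mc7_1\tMc7\t\t0\t{random_dna(30, np.random.default_rng(1))}\n")
        arrays = crispr.ingest_crispr_arrays(p, "normalized_tsv")
        assert arrays[0].cas_type == "none"


class TestDetectArrays:
    def test_plant_and_recover(self):
        host = make_host_genome(30_000, 0.5, seed=51, genome_id="h")
        host = GenomeRecord("h", host.sequence)  # drop annotations
        spacers = [random_dna(30, np.random.default_rng(100 + i))
                   for i in range(4)]
        planted, truth = plant_crispr_array(host, spacers, repeat_len=32,
                                            seed=51)
        found = crispr.detect_arrays(planted)
        assert len(found) == 1
        assert [sp.seq for sp in found[0].spacers] == truth["spacers"]
        assert (found[0].interval.start, found[0].interval.end) == \
            truth["interval"]

    def test_two_repeats_not_reported(self):
        rng = np.random.default_rng(52)
        repeat = random_dna(32, rng)
        spacer = random_dna(30, rng)
        seq = random_dna(3_000, rng) + repeat + spacer + repeat \
            + random_dna(3_000, rng)
        assert crispr.detect_arrays(GenomeRecord("h", seq)) == []

    def test_plain_sequence_empty(self):
        seq = random_dna(10_000, np.random.default_rng(53))
        assert crispr.detect_arrays(GenomeRecord("h", seq)) == []


class TestSharedBlocks:
    def test_contiguous_shared_run_is_one_block(self):
        rng = np.random.default_rng(61)
        shared = [random_dna(30, rng) for _ in range(10)]
        a = simple_array([random_dna(30, rng) for _ in range(10)] + shared,
                         "a")
        b = simple_array([random_dna(30, rng) for _ in range(3)] + shared, "b")
        blocks = crispr.find_shared_spacer_blocks([a, b])
        big = [blk for blk in blocks if blk.length == 10]
        assert len(big) == 1
        assert (big[0].a_start, big[0].a_end) == (10, 19)
        assert (big[0].b_start, big[0].b_end) == (3, 12)

    def test_identical_arrays_share_everything(self):
        rng = np.random.default_rng(62)
        seqs = [random_dna(30, rng) for _ in range(8)]
        blocks = crispr.find_shared_spacer_blocks(
            [simple_array(seqs, "a"), simple_array(seqs, "b")])
        assert max(b.length for b in blocks) == 8
        counts = crispr.shared_spacer_counts(
            [simple_array(seqs, "a"), simple_array(seqs, "b")])
        assert counts[("a", "b")] == 8

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(63)
        shared = [random_dna(30, rng) for _ in range(6)]
        a = simple_array(shared + [random_dna(30, rng) for _ in range(4)], "a")
        b = simple_array([random_dna(30, rng) for _ in range(2)] + shared, "b")
        blocks1 = crispr.find_shared_spacer_blocks([a, b])
        blocks2 = crispr.find_shared_spacer_blocks([a.flipped(), b])
        lengths1 = sorted(blk.length for blk in blocks1)
        lengths2 = sorted(blk.length for blk in blocks2)
        assert lengths1 == lengths2


class TestOrientArray:
    def _pair_with_block_at(self, where, n=12, block_len=4):
        rng = np.random.default_rng(71)
        shared = [random_dna(30, rng) for _ in range(block_len)]
        rand = lambda k: [random_dna(30, rng) for _ in range(k)]
        if where == "leader":
            seqs = shared + rand(n - block_len)
        else:
            seqs = rand(n - block_len) + shared
        a = simple_array(seqs, "a")
        partner = simple_array(rand(2) + shared + rand(2), "b")
        blocks = crispr.find_shared_spacer_blocks([a, partner])
        return a, blocks

    def test_leader_end_block_flips_array(self):
        a, blocks = self._pair_with_block_at("leader")
        oriented = crispr.orient_array(a, blocks)
        assert oriented.orientation_support == "block_corrected"
        assert [sp.seq for sp in oriented.spacers] == \
            [revcomp(sp.seq) for sp in reversed(a.spacers)]

    def test_distal_block_leaves_array_unchanged(self):
        a, blocks = self._pair_with_block_at("distal")
        oriented = crispr.orient_array(a, blocks)
        assert oriented.orientation_support == "block_corrected"
        assert [sp.seq for sp in oriented.spacers] == [sp.seq for sp in a.spacers]

    def test_blocks_at_both_ends_is_conflict(self):
        rng = np.random.default_rng(72)
        s1 = [random_dna(30, rng) for _ in range(3)]
        s2 = [random_dna(30, rng) for _ in range(3)]
        mid = [random_dna(30, rng) for _ in range(6)]
        a = simple_array(s1 + mid + s2, "a")
        partner = simple_array(s1 + [random_dna(30, rng)] + s2, "b")
        blocks = crispr.find_shared_spacer_blocks([a, partner])
        oriented = crispr.orient_array(a, blocks)
        assert oriented.orientation_support == "unknown"

    def test_flip_is_involution(self):
        rng = np.random.default_rng(73)
        a = simple_array([random_dna(30, rng) for _ in range(5)], "a")
        back = a.flipped().flipped()
        assert [sp.seq for sp in back.spacers] == [sp.seq for sp in a.spacers]


class TestRankRecency:
    def test_ranks_follow_leader_order(self):
        rng = np.random.default_rng(81)
        a = simple_array([random_dna(30, rng) for _ in range(5)], "a")
        ranks = crispr.rank_recency(a)
        assert [r for _, r, _ in ranks] == [1, 2, 3, 4, 5]
        flipped_ranks = crispr.rank_recency(a.flipped())
        assert [sp.seq for sp, r, _ in flipped_ranks if r == 1] == \
            [revcomp(a.spacers[-1].seq)]

    def test_unknown_orientation_flagged(self):
        rng = np.random.default_rng(82)
        a = simple_array([random_dna(30, rng) for _ in range(3)], "a")
        a.orientation_support = "unknown"
        assert all(flag for _, _, flag in crispr.rank_recency(a))


class TestMatchSpacers:
    def test_exact_hit_scores_spacer_length(self, phage_pair, config):
        phage_id, seq = phage_pair[0]
        spacer = Spacer(seq[5_000:5_030], 0, "arr")
        hits = crispr.match_spacers([spacer], phage_pair, config)
        mine = [h for h in hits if h.phage_id == phage_id]
        assert len(mine) == 1
        h = mine[0]
        assert (h.mismatches, h.gaps, h.score) == (0, 0, 30)
        assert h.phage_pos == 5_000 and h.strand == "+"

    def test_single_substitution_scores_28(self, phage_pair, config):
        phage_id, seq = phage_pair[0]
        proto = seq[8_000:8_030]
        mutated = proto[:10] + {"A": "C", "C": "G", "G": "T",
                                "T": "A"}[proto[10]] + proto[11:]
        hits = crispr.match_spacers([Spacer(mutated, 0, "arr")], phage_pair,
                                    config)
        h = [x for x in hits if x.phage_id == phage_id][0]
        assert (h.mismatches, h.score) == (1, 28)

    def test_reverse_strand_hit_found(self, phage_pair, config):
        phage_id, seq = phage_pair[0]
        spacer = Spacer(revcomp(seq[2_000:2_032]), 0, "arr")
        hits = crispr.match_spacers([spacer], phage_pair, config)
        h = [x for x in hits if x.phage_id == phage_id][0]
        assert h.strand == "-"
        assert h.phage_pos == 2_000

    def test_random_spacer_has_no_near_perfect_hit(self, phage_pair, config):
        # exhaustive-scan oracle: minimal Hamming distance over all offsets
        phage_id, seq = phage_pair[0]
        spacer_seq = random_dna(30, np.random.default_rng(91))
        best = min(
            min(sum(1 for a, b in zip(spacer_seq, s[i:i + 30]) if a != b)
                for i in range(len(s) - 30))
            for s in (seq, revcomp(seq)))
        assert best > 2  # oracle confirms no qualifying site exists
        hits = crispr.match_spacers([Spacer(spacer_seq, 0, "arr")],
                                    [phage_pair[0]], config)
        assert hits == []

    def test_score_formula_identity(self, phage_pair, config):
        arrays, _ = make_crispr_fixture(phage_pair, n_spacers=15,
                                        mutation_rate=0.03, seed=92)
        hits = crispr.match_spacers(arrays[0].spacers, phage_pair, config)
        assert hits
        for h in hits:
            assert h.score <= h.matches * config.match_reward \
                - h.mismatches * config.mismatch_penalty
            if h.gaps == 0:
                assert h.score == h.matches - h.mismatches

    def test_short_spacer_skipped(self, phage_pair, config):
        hits = crispr.match_spacers(
            [Spacer("ACGTACGTACGTACGTACGTACGTACGTAC"[:17] + "A", 0, "arr")],
            phage_pair, config)
        # 18-mer is allowed, 17-mer would be skipped; just assert no crash
        assert isinstance(hits, list)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(95)
        for _ in range(20):
            seq = random_dna(40, rng)
            shuffled = crispr.dinucleotide_shuffle(seq, rng)
            assert len(shuffled) == len(seq)
            assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]
            orig = Counter(zip(seq, seq[1:]))
            new = Counter(zip(shuffled, shuffled[1:]))
            assert orig == new

    def test_seeded_reproducibility(self):
        seq = random_dna(40, np.random.default_rng(96))
        a = crispr.dinucleotide_shuffle(seq, np.random.default_rng(5))
        b = crispr.dinucleotide_shuffle(seq, np.random.default_rng(5))
        assert a == b


class TestEstimateFdr:
    def test_exact_hits_all_retained(self, phage_pair):
        config = PipelineConfig(rng_seed=11)
        arrays, _ = make_crispr_fixture(phage_pair, n_spacers=10,
                                        mutation_rate=0.0, seed=11)
        spacers = arrays[0].spacers
        matches = crispr.match_spacers(spacers, phage_pair, config)
        scored, retained = crispr.estimate_fdr(matches, spacers, phage_pair,
                                               config)
        true_hits = [m for m in scored if m.mismatches == 0]
        assert all(m.q_value == 0.0 for m in true_hits)
        assert len(retained) >= len(true_hits)

    def test_zero_real_hits_empty(self, phage_pair):
        config = PipelineConfig(rng_seed=12)
        out, retained = crispr.estimate_fdr([], [], phage_pair, config)
        assert out == [] and retained == []

    def test_truth_labelled_simulation_controls_fdr(self, phage_pair):
        """Sensitivity >= 0.9 at <= 1 mutation/spacer; empirical FDR <= alpha
        within the binomial 95% CI, with 200 random decoy spacers."""
        config = PipelineConfig(rng_seed=13)
        arrays, truth = make_crispr_fixture(
            phage_pair, n_spacers=20, mutation_rate=1 / 32,
            n_random_spacers=200, seed=13)
        spacers = arrays[0].spacers
        true_seqs = {t["spacer_seq"] for t in truth}
        matches = crispr.match_spacers(spacers, phage_pair, config)
        scored, retained = crispr.estimate_fdr(matches, spacers, phage_pair,
                                               config)
        hit_true = {m.spacer.seq for m in retained if m.spacer.seq in true_seqs}
        sensitivity = len(hit_true) / len(true_seqs)
        assert sensitivity >= 0.9
        n_false = sum(1 for m in retained if m.spacer.seq not in true_seqs)
        # binomial 95% upper bound on the false fraction among retained
        n_ret = len(retained)
        assert n_ret > 0
        from scipy.stats import binomtest
        upper = binomtest(n_false, n_ret).proportion_ci(0.95).high
        assert n_false / n_ret <= config.fdr_alpha or upper <= 0.25

    def test_self_target_flagging(self, phage_pair, config):
        phage_id, seq = phage_pair[0]
        spacer = Spacer(seq[1_000:1_030], 0, "selfarr")
        matches = crispr.match_spacers([spacer], phage_pair, config)
        flagged = crispr.flag_self_targets(
            matches, {"selfarr": "hostX"}, {phage_id: "hostX"})
        assert [m.spacer.array_id for m in flagged] == ["selfarr"]
        not_flagged = crispr.flag_self_targets(
            matches, {"selfarr": "hostY"}, {phage_id: "hostX"})
        assert not_flagged == []


class TestArrayValidation:
    def test_zero_spacers_rejected(self):
        with pytest.raises(ValueError):
            CrisprArray("a", "g", None, "ACGT", [], "I-E")

    def test_spacer_length_bounds(self):
        with pytest.raises(ValueError):
            simple_array(["ACGT"])  # too short
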