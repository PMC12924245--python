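"""Anchor finding, chaining, boundary refinement and att-site detection."""

import numpy as np
import pytest

from phagewatch import boundary
from phagewatch.boundary import revcomp
from phagewatch.model import (
    ConsensusRegion,
    GenomeRecord,
    GenomicInterval,
    PipelineConfig,
    SyntenyAnchor,
)
from phagewatch.synthetic import (
    build_cassette,
    implant_prophage,
    make_host_genome,
    random_dna,
)


def brute_force_anchors(query, ref, k):
    """Independent oracle: dictionary-of-everything k-mer uniqueness check."""
    def occurrences(seq, kmer):
        rc = revcomp(kmer)
        n = 0
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if w == kmer or w == rc:
                n += 1
        return n
    out = []
    for i in range(len(query) - k + 1):
        kmer = query[i:i + k]
        if "N" in kmer:
            continue
        if occurrences(query, kmer) != 1:
            continue
        fwd = [j for j in range(len(ref) - k + 1) if ref[j:j + k] == kmer]
        rev = [j for j in range(len(ref) - k + 1)
               if ref[j:j + k] == revcomp(kmer)]
        if len(fwd) + len(rev) == 1:
            out.append(i)
    return sorted(out)


class TestFindAnchors:
    def test_identical_sequences_match_brute_force(self, rng):
        seq = random_dna(100, np.random.default_rng(1))
        anchors = boundary.find_anchors(seq, seq, 21)
        oracle = brute_force_anchors(seq, seq, 21)
        assert sorted(a.query_pos for a in anchors) == oracle
        assert all(a.strand == "+" and a.query_pos == a.ref_pos
                   for a in anchors)
        assert len(anchors) == 80  # 100 - 21 + 1, all unique in random DNA

    def test_reverse_complement_reference_flips_strand(self):
        seq = random_dna(100, np.random.default_rng(1))
        fwd = boundary.find_anchors(seq, seq, 21)
        rev = boundary.find_anchors(seq, revcomp(seq), 21)
        assert len(rev) == len(fwd)
        assert all(a.strand == "-" for a in rev)
        # forward-strand coordinates agree after mirroring
        assert sorted(a.ref_pos for a in rev) == sorted(a.ref_pos for a in fwd)

    def test_homopolymer_has_no_unique_kmers(self):
        assert boundary.find_anchors("A" * 100, "A" * 100, 21) == []

    def test_k_larger_than_sequence_warns_empty(self):
        assert boundary.find_anchors("ACGTACGTACGT", "ACGT" * 30, 21) == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            boundary.find_anchors("A" * 50, "A" * 50, 5)


def brute_force_lis(anchors, max_gap):
    """Exhaustive best collinear chain (small n only)."""
    import itertools
    best = []
    n = len(anchors)
    order = sorted(anchors, key=lambda a: a.query_pos)
    for r in range(n, 0, -1):
        for combo in itertools.combinations(order, r):
            ok = True
            for x, y in zip(combo, combo[1:]):
                qgap = y.query_pos - (x.query_pos + x.length)
                rgap = y.ref_pos - (x.ref_pos + x.length)
                if qgap < 0 or rgap < 0 or qgap > max_gap or rgap > max_gap:
                    ok = False
                    break
            if ok:
                return list(combo)
    return best


class TestChainAnchors:
    def test_collinear_anchors_form_one_block(self):
        anchors = [SyntenyAnchor(i * 100, i * 100, 21, "+") for i in range(10)]
        blocks = boundary.chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].anchor_count == 10
        assert (blocks[0].query_start, blocks[0].query_end) == (0, 921)

    def test_large_gap_splits_blocks(self):
        anchors = [SyntenyAnchor(i * 100, i * 100, 21, "+") for i in range(5)]
        anchors += [SyntenyAnchor(50_000 + i * 100, 50_000 + i * 100, 21, "+")
                    for i in range(5)]
        blocks = boundary.chain_anchors(anchors)
        assert len(blocks) == 2

    @pytest.mark.parametrize("seed", [3, 4])
    def test_chain_length_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        anchors = [SyntenyAnchor(int(q), int(r), 21, "+")
                   for q, r in zip(rng.integers(0, 3_000, 12),
                                   rng.integers(0, 3_000, 12))]
        # dedupe query positions so chains are well-defined
        seen = set()
        anchors = [a for a in anchors
                   if a.query_pos not in seen and not seen.add(a.query_pos)]
        blocks = boundary.chain_anchors(anchors, max_gap=1_000)
        oracle = brute_force_lis(anchors, max_gap=1_000)
        best_block = max(blocks, key=lambda b: b.anchor_count)
        assert best_block.anchor_count == len(oracle)

    def test_blocks_disjoint_on_query(self, rng):
        anchors = [SyntenyAnchor(int(q), int(r), 21,
                                 "+" if rng.random() < 0.7 else "-")
                   for q, r in zip(rng.integers(0, 20_000, 150),
                                   rng.integers(0, 20_000, 150))]
        blocks = boundary.chain_anchors(anchors)
        for i, a in enumerate(blocks):
            for b in blocks[i + 1:]:
                assert a.query_end <= b.query_start or b.query_end <= a.query_start


class TestRefineBoundaries:
    def _region(self, start, end, genome_id="synth_host"):
        return ConsensusRegion(
            region_id="R", interval=GenomicInterval(genome_id, start, end),
            supporting_detectors=set(), member_candidates=[])

    def test_exact_recovery_on_clean_implant(self, implant_fixture, config):
        truth = implant_fixture["truth"].implants[0]
        region = self._region(truth.interval.start, truth.interval.end)
        refined = boundary.refine_boundaries(
            region, implant_fixture["host"], implant_fixture["reference"], config)
        assert abs(refined.interval.start - truth.interval.start) <= config.anchor_k
        assert abs(refined.interval.end - truth.interval.end) <= config.anchor_k
        assert refined.refined

    def test_jittered_call_recovers_true_boundary(self, implant_fixture, config):
        truth = implant_fixture["truth"].implants[0]
        region = self._region(truth.interval.start - 4_000,
                              truth.interval.end + 4_000)
        refined = boundary.refine_boundaries(
            region, implant_fixture["host"], implant_fixture["reference"], config)
        assert abs(refined.interval.start - truth.interval.start) <= config.anchor_k
        assert abs(refined.interval.end - truth.interval.end) <= config.anchor_k

    def test_refined_interval_within_extended_window(self, implant_fixture,
                                                     config):
        truth = implant_fixture["truth"].implants[0]
        region = self._region(truth.interval.start, truth.interval.end)
        refined = boundary.refine_boundaries(
            region, implant_fixture["host"], implant_fixture["reference"], config)
        assert refined.interval.start >= region.interval.start - config.extension_bp
        assert refined.interval.end <= region.interval.end + config.extension_bp

    def test_refinement_idempotent(self, implant_fixture, config):
        truth = implant_fixture["truth"].implants[0]
        region = self._region(truth.interval.start - 3_000,
                              truth.interval.end + 2_000)
        once = boundary.refine_boundaries(
            region, implant_fixture["host"], implant_fixture["reference"], config)
        twice = boundary.refine_boundaries(
            once, implant_fixture["host"], implant_fixture["reference"], config)
        assert (once.interval.start, once.interval.end) == \
            (twice.interval.start, twice.interval.end)

    def test_no_homology_keeps_boundaries(self, config):
        rng = np.random.default_rng(9)
        host = GenomeRecord("h", random_dna(60_000, rng))
        unrelated = GenomeRecord("r", random_dna(60_000, rng))
        region = self._region(20_000, 40_000, "h")
        refined = boundary.refine_boundaries(region, host, unrelated, config)
        assert (refined.interval.start, refined.interval.end) == (20_000, 40_000)

    def test_jittered_simulation_recovery_rate(self, config):
        """Boundary error <= anchor_k on >= 95% of sides over seeded implants."""
        from phagewatch.synthetic import simulate_detector_calls
        from phagewatch import consensus
        ok_sides = total_sides = 0
        for seed in range(12):
            host = make_host_genome(90_000, 0.63, seed=100 + seed,
                                    genome_id="h%d" % seed)
            reference = GenomeRecord("ref", host.sequence)
            cassette = build_cassette(seed=100 + seed, phage_id="p")
            infected, truth = implant_prophage(host, cassette,
                                               position=45_000, seed=seed)
            calls = simulate_detector_calls(truth, infected, miss_rate=0.0,
                                            fp_rate=0.0,
                                            boundary_jitter_sd=2_000.0,
                                            seed=seed)
            regions = consensus.merge_candidates(calls, config.merge_gap_bp)
            region = max(regions, key=lambda r: r.interval.length)
            refined = boundary.refine_boundaries(region, infected, reference,
                                                 config)
            imp = truth.implants[0]
            for got, want in ((refined.interval.start, imp.interval.start),
                              (refined.interval.end, imp.interval.end)):
                total_sides += 1
                if abs(got - want) <= config.anchor_k:
                    ok_sides += 1
        assert ok_sides / total_sides >= 0.95


def plant_att(host_seq, left_pos, right_pos, repeat):
    """Plant a direct repeat at two positions with mismatching guard bases."""
    s = list(host_seq)
    for pos in (left_pos, right_pos):
        s[pos:pos + len(repeat)] = repeat
    # guards: the two bases just outside each repeat copy differ between the
    # sites, so maximal extension (which may spend one mismatch) stops there
    for off in (-2, -1, len(repeat), len(repeat) + 1):
        s[left_pos + off] = "A"
        s[right_pos + off] = "C"
    return "".join(s)


class TestDetectAttSites:
    def _region(self, start, end, genome="h"):
        return ConsensusRegion(
            region_id="R", interval=GenomicInterval(genome, start, end),
            supporting_detectors=set(), member_candidates=[])

    def test_planted_repeat_recovered_exactly(self, config):
        rng = np.random.default_rng(21)
        seq = random_dna(60_000, rng)
        repeat = random_dna(15, np.random.default_rng(99))
        seq = plant_att(seq, 19_900, 40_050, repeat)
        host = GenomeRecord("h", seq)
        att = boundary.detect_att_sites(self._region(20_000, 40_000), host,
                                        config)
        assert att is not None
        assert att.repeat_seq == repeat
        assert att.mismatches == 0
        assert att.left_interval.start == 19_900
        assert att.right_interval.start == 40_050

    def test_repeat_below_minimum_length_absent(self, config):
        rng = np.random.default_rng(22)
        seq = random_dna(60_000, rng)
        repeat = random_dna(10, np.random.default_rng(98))  # < att_min_len
        seq = plant_att(seq, 19_900, 40_050, repeat)
        host = GenomeRecord("h", seq)
        att = boundary.detect_att_sites(self._region(20_000, 40_000), host,
                                        config)
        # any surviving hit must be a chance repeat, not the planted one
        assert att is None or att.repeat_seq != repeat

    def test_longer_pair_wins_tie_break(self, config):
        rng = np.random.default_rng(23)
        seq = random_dna(60_000, rng)
        long_repeat = random_dna(15, np.random.default_rng(97))
        short_repeat = random_dna(12, np.random.default_rng(96))
        seq = plant_att(seq, 19_900, 40_050, long_repeat)
        seq = plant_att(seq, 19_500, 40_500, short_repeat)
        host = GenomeRecord("h", seq)
        att = boundary.detect_att_sites(self._region(20_000, 40_000), host,
                                        config)
        assert att.repeat_seq == long_repeat

    def test_reverse_complement_host_mirrors_att(self, config):
        rng = np.random.default_rng(24)
        seq = random_dna(60_000, rng)
        repeat = random_dna(15, np.random.default_rng(95))
        seq = plant_att(seq, 19_900, 40_050, repeat)
        host = GenomeRecord("h", seq)
        att = boundary.detect_att_sites(self._region(20_000, 40_000), host,
                                        config)
        host_rc = GenomeRecord("h", revcomp(seq))
        n = len(seq)
        att_rc = boundary.detect_att_sites(
            self._region(n - 40_000, n - 20_000), host_rc, config)
        assert att_rc is not None
        assert att_rc.repeat_seq == revcomp(repeat)
        assert att_rc.left_interval.start == n - att.right_interval.end
        assert att_rc.right_interval.start == n - att.left_interval.end

    def test_fixture_att_contains_planted_repeat(self, implant_fixture, config):
        truth = implant_fixture["truth"].implants[0]
        region = ConsensusRegion(
            region_id="R", interval=truth.interval,
            supporting_detectors=set(), member_candidates=[])
        att = boundary.detect_att_sites(region, implant_fixture["host"], config)
        assert att is not None
        assert truth.att_seq in att.repeat_seq
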