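"""Synteny-based boundary refinement and att-site detection.

A lightweight anchor-and-chain aligner stands in for a whole-genome
aligner: unique shared k-mers become anchors, anchors are chained into
collinear synteny blocks, and the prophage insertion shows up as the
longest stretch of the extended window with no homology to the
prophage-free reference. attL/attR are found as the best pair of direct
repeats in windows centred on the two boundaries.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import replace

from .model import (
    AttSite,
    ConsensusRegion,
    GenomeRecord,
    GenomicInterval,
    PipelineConfig,
    SyntenyAnchor,
    SyntenyBlock,
)

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")

#: maximum gap between consecutive anchors of one chain, on either sequence
CHAIN_GAP_BP = 5000


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:  # N mismatches everything, so N k-mers never anchor
            index[kmer].append(i)
    return index


def find_anchors(query: str, reference: str, k: int = 21) -> list[SyntenyAnchor]:
    """Exact k-mer matches unique in both sequences, on both strands.

    Uniqueness is assessed over the forward and reverse strand jointly:
    a k-mer anchors only if it occurs exactly once in the query and
    exactly once in the reference (counting both orientations).
    """
    if k < 11:
        raise ValueError("anchor k must be at least 11")
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    if k > len(query) or k > len(reference):
        logger.warning("k=%d exceeds a sequence length; no anchors", k)
        return []
    q_idx = _kmer_positions(query, k)
    r_fwd = _kmer_positions(reference, k)
    r_rev = _kmer_positions(revcomp(reference), k)
    anchors = []
    for kmer, q_pos in q_idx.items():
        if len(q_pos) != 1:
            continue
        rc = revcomp(kmer)
        # occurrences of this k-mer on either strand of each sequence
        q_occ = 1 + len(q_idx.get(rc, [])) if rc != kmer else 1
        f = r_fwd.get(kmer, [])
        r = r_rev.get(kmer, []) if rc != kmer else []
        if q_occ != 1 or len(f) + len(r) != 1:
            continue
        if f:
            anchors.append(SyntenyAnchor(q_pos[0], f[0], k, "+"))
        else:
            # position on the reverse strand; report forward-strand coordinate
            rev_pos = r[0]
            fwd_pos = len(reference) - rev_pos - k
            anchors.append(SyntenyAnchor(q_pos[0], fwd_pos, k, "-"))
    anchors.sort(key=lambda a: a.query_pos)
    return anchors


def _collapse_runs(pool: list[SyntenyAnchor], strand: str) -> list[SyntenyAnchor]:
    """Collapse same-diagonal contiguous anchors into one long pseudo-anchor.

    Near-identical sequence produces an anchor at almost every position;
    collapsing maximal exact diagonal runs keeps the chaining DP small
    without changing the chain geometry.
    """
    if strand == "+":
        keyed = sorted(pool, key=lambda a: (a.query_pos - a.ref_pos, a.query_pos))
        diag = lambda a: a.query_pos - a.ref_pos
    else:
        keyed = sorted(pool, key=lambda a: (a.query_pos + a.ref_pos, a.query_pos))
        diag = lambda a: a.query_pos + a.ref_pos
    runs: list[SyntenyAnchor] = []
    counts: list[int] = []
    for a in keyed:
        prev = runs[-1] if runs else None
        if (prev is not None and diag(prev) == diag(a)
                and a.query_pos <= prev.query_pos + prev.length):
            runs[-1] = SyntenyAnchor(
                prev.query_pos, prev.ref_pos if strand == "+"
                else a.ref_pos,
                a.query_pos + a.length - prev.query_pos, strand)
            counts[-1] += 1
        else:
            runs.append(a)
            counts.append(1)
    return runs, counts


def chain_anchors(anchors: list[SyntenyAnchor],
                  max_gap: int = CHAIN_GAP_BP) -> list[SyntenyBlock]:
    """Chain anchors into maximal-scoring collinear synteny blocks.

    Per strand, anchors are first collapsed into maximal exact diagonal
    runs, then a longest-increasing-subsequence style DP finds the best
    chain (collinear in query and reference, gaps at most ``max_gap`` on
    both sequences); chained runs are removed and the DP repeats. Every
    anchor joins at most one block.
    """
    blocks: list[SyntenyBlock] = []
    for strand in "+-":
        raw = [a for a in anchors if a.strand == strand]
        pool, pool_counts = _collapse_runs(raw, strand)
        order = sorted(range(len(pool)), key=lambda i: pool[i].query_pos)
        pool = [pool[i] for i in order]
        pool_counts = [pool_counts[i] for i in order]
        n_anchors = {id(a): c for a, c in zip(pool, pool_counts)}
        while pool:
            chain = _best_chain(pool, strand, max_gap)
            if not chain:
                break
            used = set(id(a) for a in chain)
            pool = [a for a in pool if id(a) not in used]
            q_start = min(a.query_pos for a in chain)
            q_end = max(a.query_pos + a.length for a in chain)
            r_start = min(a.ref_pos for a in chain)
            r_end = max(a.ref_pos + a.length for a in chain)
            blocks.append(SyntenyBlock(
                query_start=q_start, query_end=q_end,
                ref_start=r_start, ref_end=r_end,
                strand=strand,
                anchor_count=sum(n_anchors[id(a)] for a in chain),
                score=float(sum(a.length for a in chain)),
            ))
    # keep blocks pairwise non-overlapping on the query: best score first
    blocks.sort(key=lambda b: (-b.score, b.query_start))
    kept: list[SyntenyBlock] = []
    for b in blocks:
        if all(b.query_end <= k.query_start or k.query_end <= b.query_start
               for k in kept):
            kept.append(b)
    kept.sort(key=lambda b: b.query_start)
    return kept


def _best_chain(pool: list[SyntenyAnchor], strand: str,
                max_gap: int) -> list[SyntenyAnchor]:
    # O(n^2) DP; anchor counts here are thousands at most.
    n = len(pool)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        aj = pool[j]
        for i in range(j):
            ai = pool[i]
            qgap = aj.query_pos - (ai.query_pos + ai.length)
            if qgap < 0 or qgap > max_gap:
                continue
            if strand == "+":
                rgap = aj.ref_pos - (ai.ref_pos + ai.length)
            else:
                rgap = ai.ref_pos - (aj.ref_pos + aj.length)
            if rgap < 0 or rgap > max_gap:
                continue
            if best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    j = max(range(n), key=lambda x: best[x])
    chain = []
    while j != -1:
        chain.append(pool[j])
        j = prev[j]
    chain.reverse()
    return chain


def coverage_gaps(blocks: list[SyntenyBlock], window_len: int) -> list[tuple[int, int]]:
    """Stretches of [0, window_len) not covered by any block's query interval."""
    ivs = sorted((b.query_start, b.query_end) for b in blocks)
    gaps = []
    pos = 0
    for s, e in ivs:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < window_len:
        gaps.append((pos, window_len))
    return gaps


def refine_boundaries(region: ConsensusRegion, host: GenomeRecord,
                      reference: GenomeRecord,
                      config: PipelineConfig) -> ConsensusRegion:
    """Adjust region boundaries to the edges of flanking synteny blocks.

    The region is extended by ``extension_bp`` on both sides and anchored
    against the prophage-free reference. The insertion is the longest
    uncovered stretch of the window; the refined left boundary is the end
    of the last syntenic block before it and the right boundary the start
    of the first block after it. A side with no flanking homology keeps
    its original boundary (with a warning).
    """
    if reference.length < config.anchor_k:
        raise ValueError("reference shorter than anchor_k")
    iv = region.interval
    win_start = max(0, iv.start - config.extension_bp)
    win_end = min(host.length, iv.end + config.extension_bp)
    window = host.sequence[win_start:win_end]
    anchors = find_anchors(window, reference.sequence, config.anchor_k)
    blocks = chain_anchors(anchors)
    if not blocks:
        logger.warning("%s: no homology to reference; boundaries unchanged",
                       region.region_id)
        return replace_region(region, iv.start, iv.end, refined=True)
    gaps = coverage_gaps(blocks, len(window))
    # interior gaps only: a gap touching the window edge is flank, not insertion
    interior = [g for g in gaps if g[0] > 0 and g[1] < len(window)]
    candidates = interior or gaps
    if not candidates:
        logger.warning("%s: window fully syntenic; boundaries unchanged",
                       region.region_id)
        return replace_region(region, iv.start, iv.end, refined=True)
    gap = max(candidates, key=lambda g: g[1] - g[0])
    new_start = win_start + gap[0] if gap[0] > 0 else iv.start
    new_end = win_start + gap[1] if gap[1] < len(window) else iv.end
    if gap[0] == 0:
        logger.warning("%s: no syntenic block left of the insertion; "
                       "left boundary kept", region.region_id)
    if gap[1] == len(window):
        logger.warning("%s: no syntenic block right of the insertion; "
                       "right boundary kept", region.region_id)
    if new_end <= new_start:
        logger.warning("%s: degenerate refinement; boundaries unchanged",
                       region.region_id)
        new_start, new_end = iv.start, iv.end
    return replace_region(region, new_start, new_end, refined=True)


def replace_region(region: ConsensusRegion, start: int, end: int,
                   refined: bool = False) -> ConsensusRegion:
    new_iv = GenomicInterval(region.interval.genome_id, start, end)
    out = ConsensusRegion(
        region_id=region.region_id,
        interval=new_iv,
        supporting_detectors=set(region.supporting_detectors),
        member_candidates=[],  # members may fall outside the refined interval
        phage_gene_count=region.phage_gene_count,
        total_gene_count=region.total_gene_count,
        verdict=region.verdict,
        completeness_pct=region.completeness_pct,
        quality_tier=region.quality_tier,
        refined=refined,
    )
    return out


# ---------------------------------------------------------------------------
# att-site detection


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _extend_repeat(left_win: str, right_win: str, i: int, j: int, seed_len: int,
                   budget: int) -> tuple[int, int, int, int]:
    """Maximal direct repeat around a seed, spending at most ``budget`` mismatches.

    Returns (start offset in left window, start in right window, length,
    mismatches). Extension is greedy outward and trailing mismatches are
    trimmed so the repeat starts and ends on a match.
    """
    mm = 0
    s_i, s_j, length = i, j, seed_len
    # extend right
    while s_i + length < len(left_win) and s_j + length < len(right_win):
        a, b = left_win[s_i + length], right_win[s_j + length]
        if a == b and a != "N":
            length += 1
        elif mm < budget:
            mm += 1
            length += 1
        else:
            break
    while length > 0 and (left_win[s_i + length - 1] != right_win[s_j + length - 1]
                          or left_win[s_i + length - 1] == "N"):
        length -= 1
        mm -= 1
    # extend left
    while s_i > 0 and s_j > 0:
        a, b = left_win[s_i - 1], right_win[s_j - 1]
        if a == b and a != "N":
            s_i -= 1; s_j -= 1; length += 1
        elif mm < budget:
            mm += 1; s_i -= 1; s_j -= 1; length += 1
        else:
            break
    while length > 0 and (left_win[s_i] != right_win[s_j] or left_win[s_i] == "N"):
        s_i += 1; s_j += 1; length -= 1
        mm -= 1
    return s_i, s_j, length, mm


def detect_att_sites(region: ConsensusRegion, host: GenomeRecord,
                     config: PipelineConfig) -> AttSite | None:
    """Best pair of direct repeats in windows centred on the two boundaries.

    The highest-scoring pair with length >= ``att_min_len`` and at most
    ``att_max_mismatch`` mismatches wins; ties break on (longer repeat,
    fewer mismatches, smaller left start). Returns None when no pair
    qualifies.
    """
    half = config.att_search_bp // 2
    iv = region.interval
    l_start = max(0, iv.start - half)
    l_end = min(host.length, iv.start + half)
    r_start = max(0, iv.end - half)
    r_end = min(host.length, iv.end + half)
    if r_start < l_end:  # short region: keep windows disjoint
        mid = (l_end + r_start) // 2
        l_end = r_start = mid
    left_win = host.sequence[l_start:l_end]
    right_win = host.sequence[r_start:r_end]
    if not left_win or not right_win:
        return None

    seed_len = max(5, config.att_min_len // (config.att_max_mismatch + 1))
    seed_index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(left_win) - seed_len + 1):
        word = left_win[i:i + seed_len]
        if "N" not in word:
            seed_index[word].append(i)

    best: tuple | None = None  # (-length, mismatches, left_start, right_start, seq)
    seen: set[tuple[int, int, int]] = set()
    for j in range(len(right_win) - seed_len + 1):
        word = right_win[j:j + seed_len]
        for i in seed_index.get(word, ()):
            s_i, s_j, length, mm = _extend_repeat(
                left_win, right_win, i, j, seed_len, config.att_max_mismatch)
            if length < config.att_min_len:
                continue
            key = (s_i, s_j, length)
            if key in seen:
                continue
            seen.add(key)
            cand = (-length, mm, l_start + s_i, r_start + s_j,
                    left_win[s_i:s_i + length])
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    length = -best[0]
    left_abs, right_abs = best[2], best[3]
    return AttSite(
        left_interval=GenomicInterval(host.genome_id, left_abs, left_abs + length),
        right_interval=GenomicInterval(host.genome_id, right_abs, right_abs + length),
        repeat_seq=best[4],
        mismatches=best[1],
    )
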