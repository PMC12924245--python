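"""Pairwise intergenomic similarity and ICTV threshold clustering.

Similarity between two phage genomes follows the published whole-genome
definition: local alignments are found (here by unique-k-mer seeding and
chaining, with the inter-anchor gaps closed by exact pairwise alignment),
aligned segments are merged per genome, identical positions are counted
on each, and

    similarity_pct = 100 * (id_a + id_b) / (len_a + len_b).

Clustering at the ICTV demarcation thresholds (species 95%, genus 70%)
is single linkage, i.e. connected components of the at-or-above-threshold
graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .boundary import chain_anchors, find_anchors, revcomp
from .model import PipelineConfig

logger = logging.getLogger(__name__)

#: anchor k-mer for similarity seeding; shorter than the synteny anchor so
#: that point mutations every ~50-100 bp still leave seeds between them
SIMILARITY_K = 13


@dataclass
class SimilarityEntry:
    id_a: str
    id_b: str
    len_a: int
    len_b: int
    identities_a: int
    identities_b: int
    aligned_frac_a: float
    aligned_frac_b: float
    length_ratio: float
    similarity_pct: float


def _gap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


#: inter-anchor gaps longer than this are left uncounted (undercounts
#: identities slightly; keeps the gap-closure DP small)
MAX_GAP_ALIGN = 2000


def _count_identities(alignment) -> int:
    total = 0
    t_blocks, q_blocks = alignment.aligned
    target, query = str(alignment.target), str(alignment.query)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b and a != "N":
                total += 1
    return total


def _chain_identities(seq_a: str, seq_b: str, k: int) -> list[tuple[int, int, int]]:
    """Aligned (a_start, a_end, identities) segments between two sequences.

    One entry per synteny chain: anchors contribute exact positions and
    the gaps between consecutive anchors are closed with full pairwise
    alignment of the (short) gap substrings.
    """
    anchors = find_anchors(seq_a, seq_b, k)
    blocks = chain_anchors([a for a in anchors if a.strand == "+"])
    aligner = _gap_aligner()
    segments = []
    for block in blocks:
        chain = [a for a in anchors
                 if a.strand == "+"
                 and block.query_start <= a.query_pos
                 and a.query_pos + a.length <= block.query_end
                 and block.ref_start <= a.ref_pos
                 and a.ref_pos + a.length <= block.ref_end]
        chain.sort(key=lambda a: a.query_pos)
        # keep the chain monotone on the reference as well
        monotone = []
        last_ref = -1
        for a in chain:
            if a.ref_pos > last_ref:
                monotone.append(a)
                last_ref = a.ref_pos
        chain = monotone
        ident = 0
        prev_q_end = prev_r_end = None
        for a in chain:
            q_start, r_start = a.query_pos, a.ref_pos
            if prev_q_end is not None:
                # overlap with the previous anchor on either sequence:
                # count only the novel exact positions
                q_start = max(q_start, prev_q_end)
                r_start = max(r_start, prev_r_end)
                shift = max(q_start - a.query_pos, r_start - a.ref_pos)
                q_start = a.query_pos + shift
                r_start = a.ref_pos + shift
                gap_a = seq_a[prev_q_end:q_start]
                gap_b = seq_b[prev_r_end:r_start]
                if gap_a and gap_b and max(len(gap_a), len(gap_b)) <= MAX_GAP_ALIGN:
                    ident += _count_identities(aligner.align(gap_a, gap_b)[0])
            exact = a.query_pos + a.length - q_start
            if exact > 0:
                ident += exact
            prev_q_end = a.query_pos + a.length
            prev_r_end = a.ref_pos + a.length
        segments.append((block.query_start, block.query_end, ident))
    return segments


def _merged_span(segments: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(segments):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def pairwise_similarity(id_a: str, seq_a: str, id_b: str, seq_b: str,
                        config: PipelineConfig | None = None,
                        k: int = SIMILARITY_K) -> SimilarityEntry:
    """Whole-genome similarity between two phage sequences.

    Both orientations of ``seq_b`` are tried and the better one used, so
    the measure is invariant under reverse-complementing either input.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if set(seq_a) <= {"N"} or set(seq_b) <= {"N"}:
        logger.warning("all-N sequence in pair (%s, %s); similarity 0", id_a, id_b)
        return SimilarityEntry(id_a, id_b, len(seq_a), len(seq_b),
                               0, 0, 0.0, 0.0,
                               min(len(seq_a), len(seq_b)) / max(len(seq_a), len(seq_b)),
                               0.0)
    best = None
    for oriented in (seq_b, revcomp(seq_b)):
        segs = _chain_identities(seq_a, oriented, k)
        ident = sum(s[2] for s in segs)
        if best is None or ident > best[0]:
            best = (ident, segs)
    ident, segs = best
    span_a = _merged_span([(s, e) for s, e, _ in segs])
    # identities are counted symmetrically on the merged aligned segments
    id_a_count = id_b_count = min(ident, span_a)
    len_a, len_b = len(seq_a), len(seq_b)
    sim = 100.0 * (id_a_count + id_b_count) / (len_a + len_b)
    return SimilarityEntry(
        id_a=id_a, id_b=id_b, len_a=len_a, len_b=len_b,
        identities_a=id_a_count, identities_b=id_b_count,
        aligned_frac_a=span_a / len_a,
        aligned_frac_b=min(1.0, span_a / len_b),
        length_ratio=min(len_a, len_b) / max(len_a, len_b),
        similarity_pct=min(100.0, sim),
    )


def similarity_matrix(regions: list[tuple[str, str]],
                      config: PipelineConfig | None = None,
                      k: int = SIMILARITY_K) -> dict[tuple[str, str], SimilarityEntry]:
    """All-vs-all similarity; each unordered pair computed once.

    The diagonal is 100 by definition. Keys are ordered pairs both ways
    plus the diagonal, so ``matrix[a, b].similarity_pct`` always works.
    """
    ids = [r[0] for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    matrix: dict[tuple[str, str], SimilarityEntry] = {}
    for rid, seq in regions:
        matrix[(rid, rid)] = SimilarityEntry(
            rid, rid, len(seq), len(seq), len(seq), len(seq),
            1.0, 1.0, 1.0, 100.0)
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            ia, sa = regions[i]
            ib, sb = regions[j]
            entry = pairwise_similarity(ia, sa, ib, sb, config, k)
            matrix[(ia, ib)] = entry
            matrix[(ib, ia)] = SimilarityEntry(
                id_a=ib, id_b=ia, len_a=entry.len_b, len_b=entry.len_a,
                identities_a=entry.identities_b, identities_b=entry.identities_a,
                aligned_frac_a=entry.aligned_frac_b,
                aligned_frac_b=entry.aligned_frac_a,
                length_ratio=entry.length_ratio,
                similarity_pct=entry.similarity_pct)
    return matrix


@dataclass
class TaxonCluster:
    level: str  # "species" | "genus"
    members: frozenset[str]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_taxa(matrix: dict[tuple[str, str], SimilarityEntry],
                 species_threshold: float = 95.0,
                 genus_threshold: float = 70.0) -> list[TaxonCluster]:
    """Single-linkage clusters at the species and genus thresholds.

    Species clusters are nested inside genus clusters because the species
    threshold is the stricter of the two.
    """
    ids = sorted({a for a, _ in matrix})
    out = []
    for level, threshold in (("species", species_threshold),
                             ("genus", genus_threshold)):
        uf = _UnionFind(ids)
        for (a, b), entry in matrix.items():
            if a != b and entry.similarity_pct >= threshold:
                uf.union(a, b)
        groups: dict[str, set[str]] = {}
        for x in ids:
            groups.setdefault(uf.find(x), set()).add(x)
        for members in sorted(groups.values(), key=lambda m: sorted(m)[0]):
            out.append(TaxonCluster(level=level, members=frozenset(members)))
    return out


def matrix_to_rows(matrix: dict[tuple[str, str], SimilarityEntry]) -> list[dict]:
    """Heatmap-style TSV rows with the three per-pair alignment indicators."""
    rows = []
    seen = set()
    for (a, b), e in sorted(matrix.items()):
        if a == b or (b, a) in seen:
            continue
        seen.add((a, b))
        rows.append({
            "id_a": a, "id_b": b,
            "similarity_pct": round(e.similarity_pct, 1),
            "aligned_frac_a": round(e.aligned_frac_a, 3),
            "length_ratio": round(e.length_ratio, 3),
            "aligned_frac_b": round(e.aligned_frac_b, 3),
        })
    return rows
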