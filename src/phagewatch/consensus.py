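"""Consensus prophage calling from multi-detector candidate tables.

Candidates from the four detectors are merged when they overlap or sit
within ``merge_gap_bp`` of each other, then screened with five criteria:
(1) called by more than one detector, (2) longer than 10 kb, (3) at least
ten phage-specific genes, (4) an average-or-higher score for detectors
that report one, and (5) attachment sites, recorded as supporting
evidence. A CheckV-style quality gate keeps Medium/High/Complete tiers.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional

from .model import (
    AttEvidence,
    CandidateRegion,
    ConsensusRegion,
    Detector,
    FilterVerdict,
    GenomeRecord,
    GenomicInterval,
    PipelineConfig,
    QualityTier,
    RETAINED_TIERS,
    ScoreVerdict,
)

logger = logging.getLogger(__name__)

#: Detectors whose raw score participates in the score criterion.
SCORED_DETECTORS = {Detector.PHASTEST, Detector.VIBRANT}


def merge_candidates(candidates: list[CandidateRegion],
                     merge_gap_bp: int = 3000) -> list[ConsensusRegion]:
    """Merge overlapping or closely situated candidates into consensus regions.

    Output intervals are pairwise disjoint and separated by more than
    ``merge_gap_bp``; every candidate lands in exactly one region. Region
    ids are provisional (``<genome>:m<i>``) until :func:`finalize_regions`.
    """
    if not candidates:
        return []
    genomes = {c.interval.genome_id for c in candidates}
    if len(genomes) > 1:
        raise ValueError(
            f"candidates span multiple genomes {sorted(genomes)}; "
            "group by genome before merging")
    genome_id = genomes.pop()
    ordered = sorted(candidates, key=lambda c: (c.interval.start, c.interval.end))
    groups: list[list[CandidateRegion]] = [[ordered[0]]]
    cur_end = ordered[0].interval.end
    for cand in ordered[1:]:
        if cand.interval.start - cur_end <= merge_gap_bp:
            groups[-1].append(cand)
        else:
            groups.append([cand])
        cur_end = max(cur_end, cand.interval.end)
    regions = []
    for i, members in enumerate(groups):
        start = min(c.interval.start for c in members)
        end = max(c.interval.end for c in members)
        regions.append(ConsensusRegion(
            region_id=f"{genome_id}:m{i}",
            interval=GenomicInterval(genome_id, start, end),
            supporting_detectors={c.detector for c in members},
            member_candidates=members,
            phage_gene_count=max(c.phage_gene_count for c in members),
            total_gene_count=max(c.total_gene_count for c in members),
        ))
    return regions


def detector_score_means(candidates: list[CandidateRegion]) -> dict[Detector, float]:
    """Per-detector mean raw score over all candidates of a run.

    The score criterion compares each scored member against the run-wide
    mean of its own detector; the two score scales are not commensurable.
    """
    sums: dict[Detector, list[float]] = defaultdict(list)
    for c in candidates:
        if c.detector in SCORED_DETECTORS and c.raw_score is not None:
            sums[c.detector].append(c.raw_score)
    return {d: sum(v) / len(v) for d, v in sums.items() if v}


def apply_filters(region: ConsensusRegion, config: PipelineConfig,
                  score_means: Optional[dict[Detector, float]] = None,
                  att_present: AttEvidence = AttEvidence.UNKNOWN) -> FilterVerdict:
    """Evaluate the five selection criteria for one merged region.

    Criteria (1)-(3) are mandatory. Criterion (4) applies only when a
    scored detector (PHASTEST/VIBRANT) is among the members; a region
    passes it when any scored member reaches its detector's run-wide mean.
    Criterion (5) is recorded as evidence and only enforced under
    ``strict_all_criteria``.
    """
    score_means = score_means or {}
    multi = len(region.supporting_detectors) >= config.min_detectors
    length_ok = region.interval.length > config.min_length_bp
    genes_ok = region.phage_gene_count >= config.min_phage_genes

    scored = [c for c in region.member_candidates
              if c.detector in SCORED_DETECTORS and c.raw_score is not None
              and c.detector in score_means]
    if not scored:
        score_ok = ScoreVerdict.NOT_APPLICABLE
    elif any(c.raw_score >= score_means[c.detector] for c in scored):
        score_ok = ScoreVerdict.PASS
    else:
        score_ok = ScoreVerdict.FAIL

    if att_present is AttEvidence.UNKNOWN:
        flags = [c.has_att_flag for c in region.member_candidates
                 if c.has_att_flag is not None]
        if flags:
            att_present = AttEvidence.YES if any(flags) else AttEvidence.NO

    passed = multi and length_ok and genes_ok and score_ok is not ScoreVerdict.FAIL
    if config.strict_all_criteria:
        passed = passed and score_ok is ScoreVerdict.PASS \
            and att_present is AttEvidence.YES
    return FilterVerdict(
        multi_detector=multi,
        length_ok=length_ok,
        phage_genes_ok=genes_ok,
        score_ok=score_ok,
        att_present=att_present,
        passed=passed,
    )


def _strain_tag(genome_id: str) -> str:
    # "Bath" from e.g. "M_capsulatus_Bath" or plain ids unchanged
    return genome_id.split("/")[-1]


def finalize_regions(regions_by_genome: dict[str, list[ConsensusRegion]],
                     checkv: Optional[dict[str, tuple[float, QualityTier]]],
                     config: PipelineConfig) -> list[ConsensusRegion]:
    """Apply the quality gate and assign final ``<strain>-Rn`` region ids.

    Regions must already carry a filter verdict. When CheckV data are
    present, only Medium/High/Complete tiers survive; with no CheckV
    table the gate is skipped with a warning.
    """
    if not checkv:
        logger.warning("no CheckV table supplied; quality gate skipped")
    final: list[ConsensusRegion] = []
    for genome_id in sorted(regions_by_genome):
        kept = []
        for region in sorted(regions_by_genome[genome_id],
                             key=lambda r: r.interval.start):
            if region.verdict is None or not region.verdict.passed:
                continue
            if checkv:
                entry = checkv.get(region.region_id)
                if entry is not None:
                    region.completeness_pct, region.quality_tier = entry
                if region.quality_tier not in RETAINED_TIERS:
                    continue
            kept.append(region)
        for n, region in enumerate(kept, 1):
            region.region_id = f"{_strain_tag(genome_id)}-R{n}"
            final.append(region)
    return final


def prophage_fraction(genome: GenomeRecord,
                      final_regions: list[ConsensusRegion]) -> float:
    """Percent of the genome covered by prophage regions (merged first)."""
    if genome.length == 0:
        raise ValueError("zero-length genome")
    ivs = sorted((r.interval.start, r.interval.end) for r in final_regions
                 if r.interval.genome_id == genome.genome_id)
    if len(ivs) != sum(1 for r in final_regions):
        raise ValueError("regions from a different genome passed in")
    covered = 0
    cur_start, cur_end = None, None
    for s, e in ivs:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return 100.0 * covered / genome.length


def per_genome_summary(genomes: list[GenomeRecord],
                       final_regions: list[ConsensusRegion]) -> list[dict]:
    """One row per genome: region count and prophage DNA fraction."""
    rows = []
    for g in genomes:
        mine = [r for r in final_regions if r.interval.genome_id == g.genome_id]
        rows.append({
            "genome_id": g.genome_id,
            "n_regions": len(mine),
            "prophage_fraction_pct": round(prophage_fraction(g, mine), 2),
        })
    return rows
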