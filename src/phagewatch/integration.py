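"""Integration-site integrity: does a prophage insertion disrupt host genes?

Genes within ``flank_window_bp`` (default 1000 nt) of each refined
boundary are compared with their homologues in a prophage-free reference
strain: a homologue missing at the junction, or one whose length changed,
is disruption evidence. Duplicate copies of flank-gene products are
counted genome-wide, and tRNA/tmRNA adjacency is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import ConsensusRegion, FeatureKind, GeneFeature, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class HomologueCheck:
    gene: GeneFeature
    reference_gene: Optional[GeneFeature]
    length_preserved: Optional[bool]  # None = not applicable


@dataclass
class FlankReport:
    prophage_id: str
    side: str  # "left" | "right"
    genes: list[tuple[GeneFeature, int]]  # (gene, nearest-edge distance bp)
    excluded_hypothetical: list[GeneFeature] = field(default_factory=list)
    homologue_checks: list[HomologueCheck] = field(default_factory=list)
    duplicates: dict[str, int] = field(default_factory=dict)
    trna_adjacent: bool = False
    classification: str = "indeterminate"  # intergenic | gene_disrupting | indeterminate


def _is_hypothetical(gene: GeneFeature) -> bool:
    p = gene.product.strip().lower()
    return p == "" or p == "hypothetical protein"


def flanking_genes(prophage: ConsensusRegion,
                   host_annotation: Sequence[GeneFeature],
                   flank_window_bp: int = 1000) -> dict[str, FlankReport]:
    """Genes within the flank window of each boundary, with distances.

    A gene is included when its interval intersects
    ``[boundary - window, boundary + window]``; the distance is from the
    nearest gene edge to the boundary (0 when the gene straddles it).
    Hypothetical-protein genes are listed but excluded from homologue
    comparison. Output is independent of the annotation's ordering.
    """
    iv = prophage.interval
    reports = {}
    for side, boundary in (("left", iv.start), ("right", iv.end)):
        lo, hi = boundary - flank_window_bp, boundary + flank_window_bp
        rows = []
        for g in sorted(host_annotation,
                        key=lambda g: (g.interval.start, g.interval.end,
                                       g.feature_id)):
            gi = g.interval
            if gi.genome_id != iv.genome_id:
                continue
            if gi.end <= lo or gi.start >= hi:
                continue
            if iv.start <= gi.start and gi.end <= iv.end:
                continue  # a gene of the prophage itself, not a flank gene
            if gi.start <= boundary < gi.end:
                dist = 0
            else:
                dist = min(abs(gi.start - boundary), abs(gi.end - boundary))
            rows.append((g, dist))
        report = FlankReport(prophage_id=prophage.region_id, side=side,
                             genes=rows)
        report.excluded_hypothetical = [g for g, _ in rows if _is_hypothetical(g)]
        report.trna_adjacent = any(
            g.kind in (FeatureKind.TRNA, FeatureKind.TMRNA) for g, _ in rows)
        reports[side] = report
    return reports


def compare_with_reference(report: FlankReport,
                           reference_annotation: Sequence[GeneFeature],
                           ref_locus: Optional[GenomicInterval] = None,
                           length_tolerance_bp: int = 0) -> FlankReport:
    """Check flank genes against homologues in the prophage-free reference.

    The homologue is the gene with the same product string in the
    syntenic reference locus (the whole reference annotation when no
    locus is given). Ambiguous multi-copy products with no resolvable
    syntenic position give an indeterminate check. Length preservation is
    strict equality unless a tolerance is configured.
    """
    in_locus = [g for g in reference_annotation
                if ref_locus is None or g.interval.overlaps(ref_locus)]
    checks = []
    disrupted = False
    indeterminate = False
    for gene, _dist in report.genes:
        if _is_hypothetical(gene):
            continue
        homologues = [g for g in in_locus if g.product == gene.product]
        if not homologues:
            checks.append(HomologueCheck(gene, None, None))
            disrupted = True
            continue
        if len(homologues) > 1:
            same_len = [g for g in homologues
                        if abs(g.interval.length - gene.interval.length)
                        <= length_tolerance_bp]
            if len(same_len) == 1:
                homologues = same_len
            elif not same_len:
                # several copies, none with the junction gene's length:
                # the junction copy was truncated
                checks.append(HomologueCheck(gene, None, False))
                disrupted = True
                continue
            else:
                # several equal-length copies and no syntenic tie-break
                checks.append(HomologueCheck(gene, None, None))
                indeterminate = True
                continue
        ref_gene = homologues[0]
        preserved = (abs(ref_gene.interval.length - gene.interval.length)
                     <= length_tolerance_bp)
        checks.append(HomologueCheck(gene, ref_gene, preserved))
        if not preserved:
            disrupted = True
    report.homologue_checks = checks
    if disrupted:
        report.classification = "gene_disrupting"
    elif indeterminate:
        report.classification = "indeterminate"
    else:
        report.classification = "intergenic"
    return report


def check_reference_junction(report: FlankReport,
                             host_annotation: Sequence[GeneFeature],
                             reference_annotation: Sequence[GeneFeature],
                             ref_locus: GenomicInterval,
                             length_tolerance_bp: int = 0) -> FlankReport:
    """Disruption evidence from the opposite direction: a reference gene in
    the syntenic junction locus with no equal-length counterpart anywhere in
    the host annotation means the insertion truncated or deleted it."""
    host_products = {}
    for g in host_annotation:
        host_products.setdefault(g.product, []).append(g.interval.length)
    for rg in reference_annotation:
        if _is_hypothetical(rg) or not rg.interval.overlaps(ref_locus):
            continue
        lengths = host_products.get(rg.product, [])
        if not any(abs(L - rg.interval.length) <= length_tolerance_bp
                   for L in lengths):
            report.homologue_checks.append(HomologueCheck(rg, None, False))
            report.classification = "gene_disrupting"
    return report


def count_gene_copies(product: str,
                      host_annotation: Sequence[GeneFeature]) -> int:
    """Exact product-string copy count across the genome annotation."""
    if not product or not product.strip():
        raise ValueError("empty product string")
    return sum(1 for g in host_annotation if g.product == product)


def classify_integration(reports: dict[str, FlankReport],
                         host_annotation: Sequence[GeneFeature]) -> dict:
    """Per-prophage verdict from both flank reports.

    intergenic iff neither side shows disruption evidence; any
    gene-disrupting side dominates; otherwise indeterminate (conservative
    when one side could not be resolved). Duplicate counts cover every
    non-hypothetical flank gene.
    """
    sides = [reports["left"].classification, reports["right"].classification]
    if "gene_disrupting" in sides:
        verdict = "gene_disrupting"
    elif "indeterminate" in sides:
        verdict = "indeterminate"
    else:
        verdict = "intergenic"
    duplicates: dict[str, int] = {}
    for report in reports.values():
        for gene, _ in report.genes:
            if not _is_hypothetical(gene) and gene.product not in duplicates:
                duplicates[gene.product] = count_gene_copies(gene.product,
                                                            host_annotation)
        report.duplicates = duplicates
    return {
        "prophage_id": reports["left"].prophage_id,
        "classification": verdict,
        "trna_adjacent": reports["left"].trna_adjacent
        or reports["right"].trna_adjacent,
        "duplicates": duplicates,
    }


def integration_report_rows(summaries: Sequence[dict],
                            reports_by_prophage: dict[str, dict[str, FlankReport]]
                            ) -> list[dict]:
    """Rows for the integration-site report table."""
    rows = []
    for summary in summaries:
        pid = summary["prophage_id"]
        names = []
        for side in ("left", "right"):
            for gene, dist in reports_by_prophage[pid][side].genes:
                if not _is_hypothetical(gene):
                    names.append(f"{gene.product} ({side}, {dist} bp)")
        dup_text = "; ".join(f"{p}: {c} copies"
                             for p, c in sorted(summary["duplicates"].items()))
        rows.append({
            "prophage_id": pid,
            "classification": summary["classification"],
            "trna_adjacent": summary["trna_adjacent"],
            "neighboring_genes": "; ".join(names),
            "duplicate_counts": dup_text,
        })
    return rows
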