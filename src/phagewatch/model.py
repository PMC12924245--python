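"""Shared domain types for the prophage surveillance pipeline.

Coordinates are 0-based half-open everywhere inside the package; the
readers/writers in :mod:`phagewatch.io` convert to and from the 1-based
inclusive convention used in GFF3 and in human-facing reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional


class Detector(str, enum.Enum):
    PHASTEST = "phastest"
    PHIGARO = "phigaro"
    VIBRANT = "vibrant"
    PHISPY = "phispy"
    OTHER = "other"


class ScoreClass(str, enum.Enum):
    BELOW_AVERAGE = "below_average"
    AVERAGE = "average"
    ABOVE_AVERAGE = "above_average"
    MISSING = "missing"


class QualityTier(str, enum.Enum):
    COMPLETE = "Complete"
    HIGH = "High"
    MEDIUM = "Medium"
    LOW = "Low"
    NOT_DETERMINED = "NotDetermined"


#: CheckV tiers that keep a region in the final set (inferred from the
#: retained tiers of the published benchmark: only Medium/High appear).
RETAINED_TIERS = frozenset({QualityTier.COMPLETE, QualityTier.HIGH, QualityTier.MEDIUM})


class FeatureKind(str, enum.Enum):
    CDS = "CDS"
    TRNA = "tRNA"
    TMRNA = "tmRNA"
    REPEAT = "repeat"
    OTHER = "other"


class FunctionalCategory(str, enum.Enum):
    INTEGRASE = "integrase"
    TRANSPOSASE = "transposase"
    TERMINASE_LARGE = "terminase_large"
    TERMINASE_SMALL = "terminase_small"
    PORTAL = "portal"
    HEAD = "head"
    NECK = "neck"
    TAIL = "tail"
    TAIL_SHEATH = "tail_sheath"
    TAPE_MEASURE = "tape_measure"
    BASEPLATE = "baseplate"
    LYSIS = "lysis"
    NUCLEIC_ACID_METABOLISM = "nucleic_acid_metabolism"
    REGULATION = "regulation"
    HYPOTHETICAL = "hypothetical"
    OTHER = "other"


class Morphology(str, enum.Enum):
    MYOVIRUS = "myovirus"
    SIPHOVIRUS = "siphovirus"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named genome sequence."""

    genome_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.genome_id}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def length_kb(self) -> float:
        """Length in kb rounded half-up to one decimal, as printed in reports."""
        kb = Decimal(self.end - self.start) / Decimal(1000)
        return float(kb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.genome_id == other.genome_id
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two non-overlapping intervals (0 if they touch/overlap)."""
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class GeneFeature:
    feature_id: str
    interval: GenomicInterval
    kind: FeatureKind = FeatureKind.CDS
    product: str = ""
    category: Optional[FunctionalCategory] = None

    def __post_init__(self) -> None:
        if self.product is None:
            raise ValueError("product must not be None (empty string allowed)")


@dataclass
class GenomeRecord:
    genome_id: str
    sequence: str
    strain: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id} has an empty sequence")
        for f in self.features:
            if f.interval.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.feature_id} extends past the end of {self.genome_id}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CandidateRegion:
    """A single detector's prophage call."""

    interval: GenomicInterval
    detector: Detector
    raw_score: Optional[float] = None
    score_class: ScoreClass = ScoreClass.MISSING
    phage_gene_count: int = 0
    total_gene_count: int = 0
    has_att_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.total_gene_count and self.phage_gene_count > self.total_gene_count:
            raise ValueError(
                f"phage_gene_count {self.phage_gene_count} exceeds "
                f"total_gene_count {self.total_gene_count}"
            )


class ScoreVerdict(str, enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


class AttEvidence(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass
class FilterVerdict:
    multi_detector: bool
    length_ok: bool
    phage_genes_ok: bool
    score_ok: ScoreVerdict
    att_present: AttEvidence
    passed: bool


@dataclass
class ConsensusRegion:
    region_id: str
    interval: GenomicInterval
    supporting_detectors: set[Detector]
    member_candidates: list[CandidateRegion]
    phage_gene_count: int = 0
    total_gene_count: int = 0
    verdict: Optional[FilterVerdict] = None
    completeness_pct: Optional[float] = None
    quality_tier: QualityTier = QualityTier.NOT_DETERMINED
    refined: bool = False

    def __post_init__(self) -> None:
        for cand in self.member_candidates:
            if not (
                self.interval.start <= cand.interval.start
                and cand.interval.end <= self.interval.end
            ):
                raise ValueError(
                    f"region {self.region_id} does not cover member "
                    f"[{cand.interval.start}, {cand.interval.end})"
                )


@dataclass
class InducibilityVerdict:
    status: str  # "intact" | "defective"
    missing_blocks: list[str]
    rationale: str = ""

    def __post_init__(self) -> None:
        expect = "intact" if not self.missing_blocks else "defective"
        if self.status != expect:
            raise ValueError("status inconsistent with missing_blocks")


@dataclass
class ProphageRecord:
    region: ConsensusRegion
    genes: list[GeneFeature]
    morphology: Morphology = Morphology.UNDETERMINED
    inducibility: Optional[InducibilityVerdict] = None


@dataclass(frozen=True)
class AttSite:
    left_interval: GenomicInterval
    right_interval: GenomicInterval
    repeat_seq: str
    mismatches: int


@dataclass(frozen=True)
class SyntenyAnchor:
    query_pos: int
    ref_pos: int
    length: int
    strand: str = "+"


@dataclass
class SyntenyBlock:
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    anchor_count: int
    score: float = 0.0


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their published defaults."""

    min_detectors: int = 2
    min_length_bp: int = 10_000
    min_phage_genes: int = 10
    merge_gap_bp: int = 3_000
    extension_bp: int = 20_000
    flank_window_bp: int = 1_000
    species_threshold_pct: float = 95.0
    genus_threshold_pct: float = 70.0
    match_reward: int = 1
    mismatch_penalty: int = 1
    gap_open: int = 10
    gap_extend: int = 2
    max_mismatches: int = 2
    fdr_alpha: float = 0.05
    anchor_k: int = 21
    att_min_len: int = 11
    att_max_mismatch: int = 1
    att_search_bp: int = 2_000
    strict_all_criteria: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_detectors", "min_length_bp", "min_phage_genes", "merge_gap_bp",
            "extension_bp", "flank_window_bp", "anchor_k", "att_min_len",
            "att_search_bp", "match_reward", "mismatch_penalty", "gap_open",
            "gap_extend",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not self.species_threshold_pct > self.genus_threshold_pct:
            raise ValueError("species threshold must exceed genus threshold")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
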