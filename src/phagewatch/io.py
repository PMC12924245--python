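"""Readers and writers for the standard and detector-specific formats.

FASTA/GenBank parsing goes through Biopython; tabular formats through
pandas. GFF3 input uses 1-based inclusive coordinates and is converted to
the internal 0-based half-open convention on read; every human-facing
writer converts back.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .model import (
    AttEvidence,
    CandidateRegion,
    ConsensusRegion,
    Detector,
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    GenomicInterval,
    QualityTier,
    ScoreClass,
)

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

#: Column contract for the normalized detector table dialect.
DETECTOR_TSV_COLUMNS = [
    "genome_id", "start_1based", "end_1based", "detector",
    "raw_score", "phage_gene_count", "total_gene_count", "att_flag",
]

_GENBANK_KIND = {
    "CDS": FeatureKind.CDS,
    "tRNA": FeatureKind.TRNA,
    "tmRNA": FeatureKind.TMRNA,
    "repeat_region": FeatureKind.REPEAT,
}

_TIER_ALIASES = {
    "complete": QualityTier.COMPLETE,
    "high-quality": QualityTier.HIGH,
    "high": QualityTier.HIGH,
    "medium-quality": QualityTier.MEDIUM,
    "medium": QualityTier.MEDIUM,
    "low-quality": QualityTier.LOW,
    "low": QualityTier.LOW,
    "not-determined": QualityTier.NOT_DETERMINED,
    "notdetermined": QualityTier.NOT_DETERMINED,
}


def normalize_sequence(seq: str) -> str:
    """Upper-case and map any non-ACGTN character to N."""
    return _NON_ACGTN.sub("N", str(seq).upper())


def read_genome(path: str | Path, format: str = "fasta") -> GenomeRecord:
    """Read a single-genome FASTA or GenBank file into a GenomeRecord."""
    path = Path(path)
    if format not in {"fasta", "genbank"}:
        raise ValueError(f"unsupported genome format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except (ValueError, OSError) as exc:
        raise IOError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise IOError(f"no sequence records in {path}")
    rec = records[0]
    if len(records) > 1:
        logger.warning("%s holds %d records; using the first (%s)",
                       path, len(records), rec.id)
    seq = normalize_sequence(str(rec.seq))
    if not seq:
        raise ValueError(f"empty sequence in {path}")
    features: list[GeneFeature] = []
    if format == "genbank":
        for i, feat in enumerate(rec.features):
            kind = _GENBANK_KIND.get(feat.type)
            if feat.type in {"source", "gene"}:
                continue
            if kind is None:
                kind = FeatureKind.OTHER
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = {1: "+", -1: "-"}.get(feat.location.strand, ".")
            product = feat.qualifiers.get("product", [""])[0]
            fid = feat.qualifiers.get("locus_tag", [f"{rec.id}_f{i}"])[0]
            features.append(GeneFeature(
                feature_id=fid,
                interval=GenomicInterval(rec.id, start, end, strand),
                kind=kind,
                product=product,
            ))
    strain = rec.annotations.get("source", "") if format == "genbank" else ""
    return GenomeRecord(genome_id=rec.id, sequence=seq, strain=strain,
                        features=features)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


_GFF_KIND = {
    "CDS": FeatureKind.CDS,
    "tRNA": FeatureKind.TRNA,
    "tmRNA": FeatureKind.TMRNA,
    "repeat_region": FeatureKind.REPEAT,
    "direct_repeat": FeatureKind.REPEAT,
}


def read_annotation(path: str | Path, format: str = "gff3",
                    genome_length: Optional[int] = None) -> list[GeneFeature]:
    """Read gene annotations from GFF3 (or GenBank) into GeneFeatures.

    GFF3 rows are 1-based inclusive; they come back as 0-based half-open.
    The ``product`` attribute supplies the product string (empty if absent).
    """
    path = Path(path)
    if format == "genbank":
        return read_genome(path, "genbank").features
    if format != "gff3":
        raise ValueError(f"unsupported annotation format {format!r}")
    features: list[GeneFeature] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype == "gene":
                continue  # gene/mRNA parents duplicate their CDS children
            kind = _GFF_KIND.get(ftype, FeatureKind.OTHER)
            start = int(start1) - 1
            end = int(end1)
            att = _parse_gff3_attributes(attrs)
            fid = att.get("ID") or att.get("locus_tag") or f"{seqid}_f{counter}"
            counter += 1
            if genome_length is not None and end > genome_length:
                raise ValueError(
                    f"feature {fid} ({path}:{lineno}) ends at {end} beyond "
                    f"genome length {genome_length}")
            features.append(GeneFeature(
                feature_id=fid,
                interval=GenomicInterval(seqid, start, end,
                                         strand if strand in "+-" else "."),
                kind=kind,
                product=att.get("product", ""),
            ))
    return features


def write_annotation(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write GeneFeatures as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write("\t".join([
                iv.genome_id, "phagewatch", f.kind.value,
                str(iv.start + 1), str(iv.end), ".",
                iv.strand if iv.strand in "+-" else ".", ".", attrs,
            ]) + "\n")


_SCORE_CLASS = {s.value: s for s in ScoreClass}


def ingest_detector_table(path: str | Path,
                          dialect: str = "normalized_tsv") -> list[CandidateRegion]:
    """Read one detector-call table into CandidateRegions.

    ``normalized_tsv`` is the tested contract (columns
    ``DETECTOR_TSV_COLUMNS``, 1-based inclusive coordinates). The native
    dialects (``phigaro``, ``vibrant``, ``phispy``, ``phastest``) are
    best-effort adapters for the tools' tabular outputs.
    """
    path = Path(path)
    if dialect == "normalized_tsv":
        return _ingest_normalized(path)
    if dialect in {"phigaro", "vibrant", "phispy", "phastest"}:
        return _ingest_native(path, Detector(dialect))
    raise ValueError(f"unknown detector dialect {dialect!r}")


def _to_candidate(genome_id: str, start1: int, end1: int, detector: Detector,
                  raw_score, phage_genes, total_genes, att_flag,
                  row_label: str) -> CandidateRegion:
    try:
        interval = GenomicInterval(genome_id, int(start1) - 1, int(end1))
        score = None if pd.isna(raw_score) else float(raw_score)
        return CandidateRegion(
            interval=interval,
            detector=detector,
            raw_score=score,
            score_class=ScoreClass.MISSING if score is None else ScoreClass.AVERAGE,
            phage_gene_count=0 if pd.isna(phage_genes) else int(phage_genes),
            total_gene_count=0 if pd.isna(total_genes) else int(total_genes),
            has_att_flag=None if pd.isna(att_flag) else bool(att_flag),
        )
    except ValueError as exc:
        raise ValueError(f"{row_label}: {exc}") from exc


def _ingest_normalized(path: Path) -> list[CandidateRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    missing = set(DETECTOR_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: empty detector table", path)
        return []
    out = []
    for idx, row in df.iterrows():
        out.append(_to_candidate(
            row["genome_id"], row["start_1based"], row["end_1based"],
            Detector(str(row["detector"]).lower()),
            row["raw_score"], row["phage_gene_count"], row["total_gene_count"],
            row["att_flag"], f"{path}: row {idx + 2}"))
    return out


def _ingest_native(path: Path, detector: Detector) -> list[CandidateRegion]:
    # The tools' native column names drift across versions; accept the
    # common aliases and fall back to positional begin/end.
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None
    gcol = pick("scaffold", "genome", "genome_id", "contig", "fragment")
    bcol = pick("begin", "start", "nucleotide start")
    ecol = pick("end", "stop", "nucleotide stop")
    scol = pick("score", "total score")
    if gcol is None or bcol is None or ecol is None:
        raise ValueError(f"{path}: cannot locate genome/begin/end columns "
                         f"for dialect {detector.value}")
    out = []
    for idx, row in df.iterrows():
        out.append(_to_candidate(
            str(row[gcol]), row[bcol], row[ecol], detector,
            row[scol] if scol else float("nan"),
            float("nan"), float("nan"), float("nan"),
            f"{path}: row {idx + 2}"))
    return out


def ingest_checkv(path: str | Path) -> dict[str, tuple[float, QualityTier]]:
    """Read a CheckV quality TSV into ``{region_id: (completeness, tier)}``."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    idcol = cols.get("contig_id") or cols.get("region_id") or df.columns[0]
    ccol = cols.get("completeness")
    qcol = cols.get("checkv_quality") or cols.get("quality")
    if ccol is None or qcol is None:
        raise ValueError(f"{path}: need completeness and quality columns")
    out: dict[str, tuple[float, QualityTier]] = {}
    for _, row in df.iterrows():
        comp = float(row[ccol])
        if not (0.0 <= comp <= 100.0):
            raise ValueError(
                f"{path}: completeness {comp} for {row[idcol]} outside [0, 100]")
        tier = _TIER_ALIASES.get(str(row[qcol]).strip().lower())
        if tier is None:
            raise ValueError(f"{path}: unknown quality tier {row[qcol]!r}")
        out[str(row[idcol])] = (comp, tier)
    return out


# ---------------------------------------------------------------------------
# Region writers / readers

REGION_TSV_COLUMNS = [
    "region_id", "genome_id", "start_1based", "end_1based", "length_kb",
    "total_proteins", "phage_proteins", "completeness_pct", "quality",
    "detectors",
]


def write_regions(regions: list[ConsensusRegion], path: str | Path,
                  format: str = "tsv") -> None:
    """Write consensus regions as BED4 (half-open), GFF3 or a report TSV.

    The TSV mirrors the published report table: region name, 1-based
    position, length in kb to one decimal, protein counts, completeness
    and quality tier.
    """
    path = Path(path)
    if format == "bed":
        with open(path, "w") as fh:
            for r in regions:
                iv = r.interval
                fh.write(f"{iv.genome_id}\t{iv.start}\t{iv.end}\t{r.region_id}\n")
        return
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in regions:
                iv = r.interval
                fh.write("\t".join([
                    iv.genome_id, "phagewatch", "prophage",
                    str(iv.start + 1), str(iv.end), ".", ".", ".",
                    f"ID={r.region_id}"]) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unsupported region format {format!r}")
    rows = []
    for r in regions:
        iv = r.interval
        rows.append({
            "region_id": r.region_id,
            "genome_id": iv.genome_id,
            "start_1based": iv.start + 1,
            "end_1based": iv.end,
            "length_kb": f"{iv.length_kb():.1f}",
            "total_proteins": r.total_gene_count,
            "phage_proteins": r.phage_gene_count,
            "completeness_pct": "" if r.completeness_pct is None else r.completeness_pct,
            "quality": r.quality_tier.value,
            "detectors": ",".join(sorted(d.value for d in r.supporting_detectors)),
        })
    pd.DataFrame(rows, columns=REGION_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str | Path) -> list[ConsensusRegion]:
    """Re-ingest a region report TSV (round-trip partner of write_regions)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    out = []
    for _, row in df.iterrows():
        detectors = set()
        if isinstance(row.get("detectors"), str) and row["detectors"]:
            detectors = {Detector(d) for d in row["detectors"].split(",")}
        comp = row.get("completeness_pct")
        out.append(ConsensusRegion(
            region_id=str(row["region_id"]),
            interval=GenomicInterval(str(row["genome_id"]),
                                     int(row["start_1based"]) - 1,
                                     int(row["end_1based"])),
            supporting_detectors=detectors,
            member_candidates=[],
            phage_gene_count=int(row["phage_proteins"]),
            total_gene_count=int(row["total_proteins"]),
            completeness_pct=None if pd.isna(comp) else float(comp),
            quality_tier=QualityTier(row["quality"]),
        ))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_xmfa_blocks(path: str | Path) -> list[dict]:
    """Minimal XMFA reader for precomputed whole-genome-aligner blocks.

    Returns one dict per aligned block with per-sequence
    ``(seq_index, start_1based, end_1based, strand)`` entries.
    """
    blocks: list[dict] = []
    current: list[tuple[int, int, int, str]] = []
    header = re.compile(r"^>\s*(\d+):(\d+)-(\d+)\s*([+-])")
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith("="):
                if current:
                    blocks.append({"entries": current})
                current = []
            else:
                m = header.match(line)
                if m:
                    current.append((int(m.group(1)), int(m.group(2)),
                                    int(m.group(3)), m.group(4)))
    if current:
        blocks.append({"entries": current})
    return blocks


def sha256_of(path: str | Path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
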