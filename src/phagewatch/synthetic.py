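"""Seeded ground-truthed synthetic fixtures for every pipeline stage.

A single integer seed drives a hierarchical seed tree (one child stream
per artefact, keyed by name), so adding a fixture never shifts an
existing one and identical inputs give byte-identical output. Hosts are
i.i.d. bases at a stated GC (the default 0.63 mirrors a methanotroph
chromosome); prophage cassettes carry the ordered gene blocks a temperate
phage needs (integrase, regulation, replication, terminase, structural,
lysis) with product strings drawn from the annotation lexicon vocabulary,
att direct repeats at both junctions, and optional internal deletions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    CandidateRegion,
    Detector,
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    GenomicInterval,
    ScoreClass,
)

BASES = np.array(list("ACGT"))

#: cassette gene plan: (block, product, approximate length bp)
CASSETTE_PLAN = [
    ("integrase", "integrase", 1200),
    ("regulation", "transcriptional regulator", 700),
    ("regulation", "repressor protein CI", 700),
    ("replication", "DNA polymerase", 2400),
    ("replication", "replicative DNA helicase", 1400),
    ("replication", "DNA ligase", 1000),
    ("terminase", "large terminase subunit", 1700),
    ("terminase", "small terminase subunit", 550),
    ("structural", "portal protein", 1500),
    ("structural", "major head protein", 1100),
    ("structural", "head-tail connector protein", 500),
    ("structural", "tail length tape measure protein", 2600),
    ("structural", "tail protein", 900),
    ("lysis", "endolysin", 550),
    ("lysis", "Rz-like spanin", 350),
]

HOST_PRODUCTS = [
    "methane monooxygenase subunit A",
    "methanol dehydrogenase large subunit",
    "ribosomal protein S4",
    "DNA gyrase subunit B",
    "elongation factor Tu",
    "ATP synthase subunit beta",
    "formaldehyde-activating enzyme",
    "hypothetical protein",
    "hypothetical protein",
    "citrate synthase",
]


def child_rng(seed: int, *key: str) -> np.random.Generator:
    """Deterministic child generator for a named artefact under a root seed."""
    tags = [zlib.crc32(k.encode()) for k in key]
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=tuple(tags))
    return np.random.default_rng(ss)


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@dataclass
class PhageCassette:
    phage_id: str
    seq: str
    genes: list[tuple[str, int, int, str]]  # (product, start, end, block)
    blocks: dict[str, tuple[int, int]]
    myovirus: bool = False


@dataclass
class Implant:
    phage_id: str
    interval: GenomicInterval
    att_seq: str
    degraded: bool = False
    deleted_blocks: tuple[str, ...] = ()
    disrupted_gene: str | None = None


@dataclass
class SyntheticTruth:
    host_id: str
    rng_seed: int
    implants: list[Implant] = field(default_factory=list)
    protospacer_sources: list[dict] = field(default_factory=list)
    detector_calls: list[CandidateRegion] = field(default_factory=list)


def make_host_genome(length: int, gc: float = 0.63, seed: int = 0,
                     genome_id: str = "host", gene_every: int = 2500
                     ) -> GenomeRecord:
    """Random host chromosome with sprinkled CDS/tRNA annotations."""
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    rng = child_rng(seed, "host", genome_id)
    seq = random_dna(length, rng, gc)
    features = []
    pos = rng.integers(200, 800)
    i = 0
    while pos + 1500 < length:
        gene_len = int(rng.integers(600, 1800))
        if rng.random() < 0.07:
            kind = FeatureKind.TRNA
            product = f"tRNA-{rng.choice(['Thr', 'Phe', 'Leu', 'Gly'])}"
            gene_len = int(rng.integers(72, 90))
        else:
            kind = FeatureKind.CDS
            product = str(rng.choice(HOST_PRODUCTS))
        end = min(pos + gene_len, length)
        features.append(GeneFeature(
            feature_id=f"{genome_id}_g{i:04d}",
            interval=GenomicInterval(genome_id, int(pos), int(end),
                                     "+" if rng.random() < 0.5 else "-"),
            kind=kind, product=product))
        pos = end + int(rng.integers(gene_every // 2, gene_every))
        i += 1
    return GenomeRecord(genome_id=genome_id, sequence=seq, features=features)


def build_cassette(seed: int = 0, phage_id: str = "phageA",
                   myovirus: bool = False, gc: float = 0.55,
                   intergenic_bp: int = 250) -> PhageCassette:
    """A temperate-phage gene cassette with the ordered essential blocks."""
    rng = child_rng(seed, "cassette", phage_id)
    plan = list(CASSETTE_PLAN)
    if myovirus:
        # contractile tail: sheath + baseplate instead of a naked tape measure
        plan.insert(13, ("structural", "tail sheath protein", 1400))
        plan.insert(14, ("structural", "baseplate protein", 800))
    pieces = []
    genes = []
    blocks: dict[str, list[int]] = {}
    pos = 0
    for block, product, approx_len in plan:
        gap = int(rng.integers(intergenic_bp // 2, intergenic_bp * 2))
        pieces.append(random_dna(gap, rng, gc))
        pos += gap
        gene_len = int(approx_len + rng.integers(-approx_len // 10,
                                                 approx_len // 10 + 1))
        pieces.append(random_dna(gene_len, rng, gc))
        genes.append((product, pos, pos + gene_len, block))
        blocks.setdefault(block, [pos, pos + gene_len])
        blocks[block][1] = pos + gene_len
        pos += gene_len
    pieces.append(random_dna(int(rng.integers(200, 500)), rng, gc))
    seq = "".join(pieces)
    return PhageCassette(
        phage_id=phage_id, seq=seq, genes=genes,
        blocks={k: (v[0], v[1]) for k, v in blocks.items()},
        myovirus=myovirus)


def degrade_prophage(cassette: PhageCassette, blocks_to_delete: set[str],
                     seed: int = 0) -> PhageCassette:
    """Excise named gene blocks (an internal-deletion pseudo-prophage)."""
    unknown = set(blocks_to_delete) - set(cassette.blocks)
    if unknown:
        raise ValueError(f"unknown blocks {sorted(unknown)}")
    if not blocks_to_delete:
        return cassette
    if set(blocks_to_delete) >= set(cassette.blocks):
        raise ValueError("cannot delete every block (empty cassette)")
    cut = sorted(cassette.blocks[b] for b in blocks_to_delete)
    merged: list[list[int]] = []
    for s, e in cut:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    keep_iv = []
    pos = 0
    for s, e in merged:
        if s > pos:
            keep_iv.append((pos, s))
        pos = e
    if pos < len(cassette.seq):
        keep_iv.append((pos, len(cassette.seq)))
    seq = "".join(cassette.seq[s:e] for s, e in keep_iv)

    def remap(x: int) -> int | None:
        off = 0
        for s, e in keep_iv:
            if s <= x <= e:
                return off + (x - s)
            off += e - s
        return None

    genes = []
    for product, gs, ge, block in cassette.genes:
        if block in blocks_to_delete:
            continue
        ns, ne = remap(gs), remap(ge)
        if ns is None or ne is None or ne <= ns:
            continue
        genes.append((product, ns, ne, block))
    blocks = {}
    for b, (bs, be) in cassette.blocks.items():
        if b in blocks_to_delete:
            continue
        ns, ne = remap(bs), remap(be)
        if ns is not None and ne is not None and ne > ns:
            blocks[b] = (ns, ne)
    return PhageCassette(phage_id=cassette.phage_id, seq=seq, genes=genes,
                         blocks=blocks, myovirus=cassette.myovirus)


def implant_prophage(host: GenomeRecord, cassette: PhageCassette,
                     position: int | None = None, att_len: int = 15,
                     seed: int = 0, disrupt_gene: bool = False,
                     truth: SyntheticTruth | None = None
                     ) -> tuple[GenomeRecord, SyntheticTruth]:
    """Insert a cassette flanked by att direct repeats into a host genome.

    The implant occupies ``[position, position + att + cassette + att)``;
    host features downstream shift by the insert length and the truth
    record is updated. Without ``disrupt_gene`` the position (when chosen
    automatically) falls between host genes; with it, mid-CDS.
    """
    rng = child_rng(seed, "implant", host.genome_id, cassette.phage_id)
    if truth is None:
        truth = SyntheticTruth(host_id=host.genome_id, rng_seed=seed)
    if position is None:
        position = _pick_position(host, rng, disrupt_gene)
    disrupted = None
    for g in host.features:
        if g.interval.start < position < g.interval.end:
            disrupted = g.product
    if disrupt_gene and disrupted is None:
        raise ValueError(f"position {position} is not inside a gene")
    att = random_dna(att_len, rng, 0.5)
    insert = att + cassette.seq + att
    for imp in truth.implants:
        if imp.interval.genome_id == host.genome_id \
                and not (position >= imp.interval.end
                         or position <= imp.interval.start):
            raise ValueError("implants overlap")
    new_seq = host.sequence[:position] + insert + host.sequence[position:]
    shift = len(insert)
    features = []
    for g in host.features:
        iv = g.interval
        if iv.end <= position:
            features.append(g)
        elif iv.start >= position:
            features.append(replace(g, interval=GenomicInterval(
                iv.genome_id, iv.start + shift, iv.end + shift, iv.strand)))
        else:
            # gene split by the insertion: keep the upstream fragment only
            features.append(replace(g, interval=GenomicInterval(
                iv.genome_id, iv.start, position, iv.strand)))
    offset = position + att_len
    for j, (product, gs, ge, _block) in enumerate(cassette.genes):
        features.append(GeneFeature(
            feature_id=f"{cassette.phage_id}_g{j:02d}",
            interval=GenomicInterval(host.genome_id, offset + gs, offset + ge, "+"),
            kind=FeatureKind.CDS, product=product))
    features.sort(key=lambda g: g.interval.start)
    new_host = GenomeRecord(genome_id=host.genome_id, sequence=new_seq,
                            strain=host.strain, features=features)
    # earlier implants downstream of this position shift too
    for imp in truth.implants:
        if imp.interval.start >= position:
            imp.interval = GenomicInterval(
                imp.interval.genome_id, imp.interval.start + shift,
                imp.interval.end + shift)
    full_blocks = {"integrase", "regulation", "replication", "terminase",
                   "structural", "lysis"}
    missing = tuple(sorted(full_blocks - set(cassette.blocks)))
    truth.implants.append(Implant(
        phage_id=cassette.phage_id,
        interval=GenomicInterval(host.genome_id, position, position + shift),
        att_seq=att,
        degraded=bool(missing),
        deleted_blocks=missing,
        disrupted_gene=disrupted,
    ))
    truth.implants.sort(key=lambda i: i.interval.start)
    return new_host, truth


def _pick_position(host: GenomeRecord, rng: np.random.Generator,
                   disrupt_gene: bool) -> int:
    margin = 25_000
    for _ in range(200):
        pos = int(rng.integers(margin, host.length - margin))
        inside = [g for g in host.features
                  if g.interval.start < pos < g.interval.end]
        if not disrupt_gene and not inside:
            return pos
        # disruption of a hypothetical protein is invisible to the flank
        # rules (they skip hypotheticals), so cut a named gene
        if disrupt_gene and inside \
                and inside[0].product.strip().lower() not in (
                    "", "hypothetical protein"):
            return pos
    raise RuntimeError("could not find a suitable implant position")


DEFAULT_DETECTORS = (Detector.PHASTEST, Detector.PHIGARO,
                     Detector.VIBRANT, Detector.PHISPY)

_SCORE_MODEL = {  # (true-call mean, false-positive mean, sd); scored tools only
    Detector.PHASTEST: (110.0, 60.0, 15.0),
    Detector.VIBRANT: (18.0, 6.0, 3.0),
}


def simulate_detector_calls(truth: SyntheticTruth, host: GenomeRecord,
                            miss_rate: float = 0.15, fp_rate: float = 0.5,
                            boundary_jitter_sd: float = 1500.0,
                            detectors=DEFAULT_DETECTORS,
                            seed: int = 0) -> list[CandidateRegion]:
    """Noisy multi-detector call tables over the implant truth.

    Each detector reports each implant with probability ``1 - miss_rate``
    with Gaussian boundary jitter; false positives arrive at ``fp_rate``
    per 100 kb of non-implant sequence with low phage-gene counts and
    below-average scores. The generated calls are also stored on the
    truth object.
    """
    if not (0 <= miss_rate < 1) or not (0 <= fp_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = child_rng(seed, "detectors", truth.host_id)
    calls: list[CandidateRegion] = []
    n_genes = 15
    for det in detectors:
        for imp in truth.implants:
            if rng.random() < miss_rate:
                continue
            jitter = rng.normal(0, boundary_jitter_sd, size=2) \
                if boundary_jitter_sd > 0 else np.zeros(2)
            start = int(round(imp.interval.start + jitter[0]))
            end = int(round(imp.interval.end + jitter[1]))
            start = max(0, min(start, host.length - 2))
            end = max(start + 1000, min(end, host.length))
            score = None
            if det in _SCORE_MODEL:
                mu, _, sd = _SCORE_MODEL[det]
                score = float(np.round(rng.normal(mu, sd), 1))
            calls.append(CandidateRegion(
                interval=GenomicInterval(host.genome_id, start, end),
                detector=det, raw_score=score,
                score_class=ScoreClass.MISSING if score is None
                else ScoreClass.AVERAGE,
                phage_gene_count=int(n_genes - rng.integers(0, 3)),
                total_gene_count=int(n_genes + rng.integers(2, 8)),
            ))
        n_fp = rng.poisson(fp_rate * host.length / 100_000)
        for _ in range(n_fp):
            length = int(rng.integers(8_000, 30_000))
            start = int(rng.integers(0, max(1, host.length - length)))
            iv = GenomicInterval(host.genome_id, start, start + length)
            if any(iv.overlaps(imp.interval) for imp in truth.implants):
                continue
            score = None
            if det in _SCORE_MODEL:
                mu_fp = _SCORE_MODEL[det][1]
                sd = _SCORE_MODEL[det][2]
                score = float(np.round(rng.normal(mu_fp, sd), 1))
            calls.append(CandidateRegion(
                interval=iv, detector=det, raw_score=score,
                score_class=ScoreClass.MISSING if score is None
                else ScoreClass.AVERAGE,
                phage_gene_count=int(rng.integers(2, 8)),
                total_gene_count=int(rng.integers(10, 20)),
            ))
    truth.detector_calls = calls
    return calls


def make_crispr_fixture(phages: list[tuple[str, str]], n_spacers: int = 20,
                        mutation_rate: float = 0.0, n_decoy_arrays: int = 1,
                        seed: int = 0, spacer_len: int = 32,
                        n_random_spacers: int | None = None,
                        shared_block_len: int = 0):
    """CRISPR arrays whose spacers sample protospacers from given phages.

    Returns ``(arrays, truth_rows)``: the first array holds ``n_spacers``
    protospacer-derived spacers (per-base ``mutation_rate``) interleaved
    with random spacers; decoy arrays are fully random. Truth rows record
    (spacer_seq, phage_id, pos, n_mutations). When ``shared_block_len``
    is positive, that many distal spacers of the first array are copied
    into the distal end of the second array (an ancestral shared block).
    """
    from .crispr import CrisprArray, Spacer

    if not phages:
        raise ValueError("phages must be non-empty")
    if n_spacers < 1:
        raise ValueError("n_spacers must be at least 1")
    rng = child_rng(seed, "crispr")
    if n_random_spacers is None:
        n_random_spacers = n_spacers // 2
    truth_rows = []
    entries = []  # (seq, is_protospacer)
    for i in range(n_spacers):
        phage_id, phage_seq = phages[int(rng.integers(len(phages)))]
        pos = int(rng.integers(0, len(phage_seq) - spacer_len))
        proto = phage_seq[pos:pos + spacer_len]
        seq = list(proto)
        n_mut = 0
        for b in range(spacer_len):
            if rng.random() < mutation_rate:
                options = [x for x in "ACGT" if x != seq[b]]
                seq[b] = options[int(rng.integers(3))]
                n_mut += 1
        seq = "".join(seq)
        entries.append((seq, True))
        truth_rows.append({"spacer_seq": seq, "phage_id": phage_id,
                           "pos": pos, "n_mutations": n_mut})
    for _ in range(n_random_spacers):
        entries.append((random_dna(spacer_len, rng), False))
    order = rng.permutation(len(entries))
    arrays = []
    main_id = "synthetic_array0"
    spacers = [Spacer(entries[k][0], i, main_id)
               for i, k in enumerate(order)]
    arrays.append(CrisprArray(
        array_id=main_id, genome_id="synthetic_host", interval=None,
        repeat_consensus=random_dna(32, child_rng(seed, "repeat")),
        spacers=spacers, cas_type="I-E"))
    for d in range(n_decoy_arrays):
        aid = f"synthetic_decoy{d}"
        n = int(rng.integers(max(2, n_spacers // 2), n_spacers + 1))
        dsp = [Spacer(random_dna(spacer_len, rng), i, aid) for i in range(n)]
        if d == 0 and shared_block_len > 0:
            src = arrays[0].spacers[-shared_block_len:]
            tail = [Spacer(sp.seq, 0, aid) for sp in src]
            dsp = dsp[:-shared_block_len] if len(dsp) > shared_block_len else []
            dsp = dsp + tail
            dsp = [Spacer(sp.seq, i, aid) for i, sp in enumerate(dsp)]
        arrays.append(CrisprArray(
            array_id=aid, genome_id=f"decoy_host{d}", interval=None,
            repeat_consensus=random_dna(32, child_rng(seed, "repeat", str(d))),
            spacers=dsp, cas_type="none"))
    return arrays, truth_rows


def plant_crispr_array(host: GenomeRecord, spacer_seqs: list[str],
                       repeat_len: int = 32, position: int | None = None,
                       seed: int = 0) -> tuple[GenomeRecord, dict]:
    """Write a physical repeat-spacer-repeat array into a host sequence.

    Returns the modified genome and a truth dict with the array interval,
    repeat and spacer list. An AT-rich leader is placed on the left so
    the built-in detector orients the array as planted.
    """
    rng = child_rng(seed, "plant_array", host.genome_id)
    repeat = random_dna(repeat_len, rng, 0.5)
    leader = random_dna(150, rng, 0.18)  # AT-rich leader
    body = leader + repeat + "".join(s + repeat for s in spacer_seqs)
    if position is None:
        position = host.length // 2
    seq = host.sequence[:position] + body + host.sequence[position:]
    start = position + len(leader)
    truth = {
        "interval": (start, start + len(body) - len(leader)),
        "repeat": repeat,
        "spacers": list(spacer_seqs),
    }
    new_host = GenomeRecord(genome_id=host.genome_id, sequence=seq,
                            strain=host.strain, features=[])
    return new_host, truth
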