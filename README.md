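# phagewatch

Prophage surveillance for methanotroph genomes.

Industrial methane bioconversion runs *Methylococcus*-centred consortia in
open, non-sterile bioreactors, where a prophage switching to the lytic
cycle can wipe out a production run. `phagewatch` implements a desk-scale,
fully testable version of the genomic surveillance workflow used to audit
such strains: it consolidates prophage calls from several detection tools
into a vetted consensus set, refines insertion boundaries against a
prophage-free reference, detects *att* attachment sites, judges each
prophage's morphology and lytic competence from its gene content, clusters
prophages at the ICTV species/genus thresholds, tests CRISPR spacer
repertoires against the prophage set with empirical FDR control, and
checks whether insertions disrupted host genes.

## The core procedures

**Consensus calling.** Candidate regions from PHASTEST / Phigaro /
VIBRANT / PhiSpy (ingested, never run) are merged when overlapping or
within `merge_gap_bp` (3 kb), then screened with five criteria: (1)
called by more than one detector, (2) length > 10 kb, (3) ≥ 10
phage-specific genes, (4) an average-or-higher score for detectors that
report one (compared per detector against the run-wide mean), and (5)
*att* sites, recorded as evidence. A CheckV-style quality gate keeps
Medium/High/Complete tiers. Final regions are named `<strain>-R1..Rn` by
genomic position.

**Boundary refinement.** Each region ± 20 kb is anchored against a
prophage-free reference with unique shared *k*-mers (k = 21), anchors are
chained into collinear synteny blocks, and the insertion is the longest
unanchored stretch; the refined boundaries are the flanking block edges.
attL/attR are the best pair of direct repeats (≥ 11 bp, ≤ 1 mismatch) in
2-kb windows centred on the boundaries.

**Intergenomic similarity.** For prophages *a*, *b* with merged aligned
segments carrying `id_a`, `id_b` identical positions,

```
similarity = 100 · (id_a + id_b) / (len_a + len_b)
```

with single-linkage clustering at 95% (species) and 70% (genus).

**CRISPR immunity.** Spacers (leader-proximal index 0 = most recently
acquired) are matched against prophage sequences on both strands under
the costs match +1, mismatch −1, gap open 10, gap extend 2, keeping
near-perfect hits (≤ 2 mismatches). False discovery is controlled
empirically with dinucleotide-shuffled decoy spacers at q ≤ 0.05.
Shared spacer blocks between strains correct array orientation: ancestral
blocks belong at the leader-distal end.

**Integration sites.** Genes within 1000 nt of a refined boundary
(hypothetical proteins excluded) are compared with their product-string
homologues in the reference strain, including lengths; a missing or
truncated homologue marks the insertion gene-disrupting, and duplicate
copies and tRNA/tmRNA adjacency are reported.

## Worked example

Everything is runnable offline from a seeded synthetic fixture:

```
phagewatch simulate --out demo --seed 7 --n-implants 2
phagewatch run-all --config demo/run.yaml --out demo_out --seed 7
```

prints the per-stage record counts

```
{"candidates": 13, "merged": 4, "filtered": 2, "final": 2,
 "spacer_matches": 8, "spacer_matches_retained": 8}
```

Thirteen noisy detector calls (including low-scoring false positives)
collapse to four merged regions; the five criteria discard the
single-detector false positives, and the two implanted prophages survive.
`demo_out/regions.tsv` holds the report table:

```
region_id      start_1based  end_1based  length_kb  total/phage proteins  detectors
synth_host-R1  66667         88873       22.2       21/15                 phastest,phigaro,phispy,vibrant
synth_host-R2  155540        180373      24.8       19/14                 phastest,phigaro,phispy,vibrant
```

The refined coordinates agree with the implant ground truth
(`demo/truth.json`: implants at 66,666–88,873 and 155,539–180,373,
0-based) to within one base. `prophage_annotation.tsv` classifies R1 as a
siphovirus (tape measure protein, no tail sheath) and R2 as a myovirus
(tail sheath present), both with all five essential gene blocks —
`intact`. `crispr_matches.tsv` lists every protospacer-derived spacer
hitting its source prophage with score = spacer length (e.g. 32 matches,
0 mismatches, score 32, q = 0, retained), and `similarity.tsv` shows the
two unrelated cassettes at 0.3% intergenomic similarity — different
genera, as expected.

A transcription of the published 11-prophage *Methylococcus* benchmark
(region coordinates, gene content at product level, similarity values,
integration notes) ships in `phagewatch.benchmark` and backs the
annotation-rule tests: nine prophages intact, KN2-R2 and McNor-R1
defective. Sequence-level benchmark checks need the public assemblies
under `benchmark_data/` (not included): `benchmark_data/prophages/*.fasta`
with the eleven region sequences.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic fixture from the seed, runs the complete
pipeline end to end (consensus → refinement → att → annotation →
similarity → CRISPR/FDR → integration → report) and writes the result
summary JSON to `--out`.
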