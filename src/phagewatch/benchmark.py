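"""Published 11-prophage Methylococcus benchmark, transcribed at desk scale.

Nine public *Methylococcus* genomes carry eleven predicted prophage
regions in five strains. This module packages the published summary
tables — region coordinates (1-based inclusive, as printed), protein
counts, completeness/quality, detector tallies, pairwise similarity
values, integration-site notes — plus a transcription of each prophage's
annotated gene content at the product-string level, so the rule layer can
be exercised without downloading assemblies. Sequences themselves are NOT
included; sequence-level benchmark checks require the public assemblies.
"""

from __future__ import annotations

from .model import Morphology

#: strains analysed; five carry at least one prophage region
STRAINS = [
    "Bath", "KN2", "IO1", "McNor", "16-5", "MIR", "IM1", "BH", "Mc7",
]
STRAINS_WITH_PROPHAGES = ["Bath", "KN2", "IO1", "McNor", "16-5"]

#: (region_id, start_1based, end_1based, printed_length_kb,
#:  total_proteins, phage_proteins, completeness_pct, quality)
REGIONS = [
    ("Bath-R1", 2_818_869, 2_875_600, 56.7, 57, 17, 76.28, "Medium"),
    ("Bath-R2", 3_090_981, 3_136_586, 45.6, 63, 27, 100.0, "High"),
    ("KN2-R1", 1_828_593, 1_899_999, 71.4, 81, 22, 60.97, "Medium"),
    ("KN2-R2", 2_309_080, 2_345_124, 36.0, 45, 16, 60.91, "Medium"),
    ("IO1-R1", 2_502_234, 2_549_530, 47.3, 65, 26, 100.0, "High"),
    ("McNor-R1", 491_588, 520_685, 29.1, 33, 13, 70.28, "Medium"),
    ("McNor-R2", 1_493_609, 1_539_485, 45.9, 58, 21, 73.14, "Medium"),
    ("McNor-R3", 1_900_782, 1_941_935, 41.2, 53, 16, 69.54, "Medium"),
    ("16-5-R1", 1_897_271, 1_964_996, 67.7, 90, 20, 100.0, "High"),
    ("16-5-R2", 2_518_532, 2_564_410, 45.9, 60, 29, 100.0, "High"),
    ("16-5-R3", 3_229_289, 3_281_743, 52.5, 68, 18, 100.0, "High"),
]

#: initial detector tallies before merging/filtering
DETECTOR_CANDIDATE_COUNTS = {
    "phigaro": 21,
    "phispy": 19,
    "phastest": 14,
    "vibrant": 14,
}
TOTAL_CANDIDATES = 68

#: published pairwise intergenomic similarity values (percent)
SIMILARITY_PAIRS = {
    ("KN2-R2", "McNor-R3"): 84.5,
    ("16-5-R1", "16-5-R3"): 68.8,
    ("KN2-R1", "McNor-R2"): 61.5,
    ("IO1-R1", "Bath-R2"): 68.8,
    ("16-5-R2", "McNor-R1"): 29.6,
}

_SIPHO_CORE = [
    "transcriptional regulator", "DNA polymerase", "replicative DNA helicase",
    "large terminase subunit", "small terminase subunit", "portal protein",
    "major head protein", "head-tail connector protein",
    "tail length tape measure protein", "tail protein", "endolysin",
]
_MYO_CORE = [
    "transposase", "transcriptional regulator", "DNA polymerase",
    "DNA ligase", "large terminase subunit", "small terminase subunit",
    "portal protein", "major head protein", "head-tail connector protein",
    "tail sheath protein", "tail protein", "baseplate protein", "endolysin",
]

#: product-level transcription of each prophage's annotated gene content.
#: KN2-R2 lost its right side (regulatory genes and integrase); McNor-R1
#: lost ~half of its centre (transposase/integrase, replication and
#: regulation genes, and head/packaging structural components).
GENE_PRODUCTS = {
    "Bath-R1": ["integrase"] + _SIPHO_CORE,
    "Bath-R2": _MYO_CORE,
    "KN2-R1": ["integrase"] + _SIPHO_CORE,
    "KN2-R2": ["DNA polymerase", "replicative DNA helicase",
               "large terminase subunit", "small terminase subunit",
               "portal protein", "major head protein",
               "head-tail connector protein",
               "tail length tape measure protein", "tail protein",
               "endolysin"],
    "IO1-R1": _MYO_CORE,
    "McNor-R1": ["tail length tape measure protein", "tail protein",
                 "tail fiber protein", "endolysin",
                 "hypothetical protein"],
    "McNor-R2": ["integrase"] + _SIPHO_CORE,
    "McNor-R3": ["integrase"] + _SIPHO_CORE,
    "16-5-R1": ["integrase"] + _SIPHO_CORE,
    "16-5-R2": ["transposase"] + _SIPHO_CORE + ["Rz-like spanin"],
    "16-5-R3": ["integrase"] + _SIPHO_CORE,
}

#: published morphology calls (tail-gene rules)
MORPHOLOGY = {
    "Bath-R1": Morphology.SIPHOVIRUS,
    "Bath-R2": Morphology.MYOVIRUS,
    "KN2-R1": Morphology.SIPHOVIRUS,
    "KN2-R2": Morphology.SIPHOVIRUS,
    "IO1-R1": Morphology.MYOVIRUS,
    "McNor-R1": Morphology.SIPHOVIRUS,
    "McNor-R2": Morphology.SIPHOVIRUS,
    "McNor-R3": Morphology.SIPHOVIRUS,
    "16-5-R1": Morphology.SIPHOVIRUS,
    "16-5-R2": Morphology.SIPHOVIRUS,
    "16-5-R3": Morphology.SIPHOVIRUS,
}

DEFECTIVE_REGIONS = {"KN2-R2", "McNor-R1"}

#: integration-site notes: (region, gene, side, preserved, copies in host)
INTEGRATION_NOTES = [
    ("Bath-R1", "ssrA", "left", True, 1),
    ("Bath-R2", "tRNA-Thr", "left", True, 3),
    ("KN2-R1", "tRNA-Phe", "right", True, 1),
]

#: prophage DNA fraction of the 16-5 genome, percent
FRACTION_16_5_PCT = 3.82
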