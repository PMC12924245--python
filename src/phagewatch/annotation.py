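"""Rule-based gene categorization, morphology and inducibility calls.

The decision layer of database-driven phage annotation is re-expressed as
a keyword lexicon over product strings, so the rules run on any
GenBank/GFF3 annotation without external databases. Morphology follows
the tail-gene rules (a tail sheath protein marks a contractile-tailed
myovirus; a tape measure protein without a sheath marks a siphovirus),
and inducibility requires the five gene blocks a temperate phage needs to
re-enter the lytic cycle.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .model import (
    ConsensusRegion,
    FunctionalCategory,
    GeneFeature,
    InducibilityVerdict,
    Morphology,
    ProphageRecord,
)

#: The five essential gene blocks checked by :func:`assess_inducibility`.
ESSENTIAL_BLOCKS = ("integrase", "structural", "terminase", "lysis",
                    "nucleic_acid_metabolism")

_STRUCTURAL_REQUIRED = (
    FunctionalCategory.PORTAL,
    FunctionalCategory.HEAD,
    FunctionalCategory.TAIL,
)


@lru_cache(maxsize=1)
def _default_lexicon() -> tuple[tuple[str, FunctionalCategory], ...]:
    text = resources.files("phagewatch.data").joinpath(
        "category_lexicon.tsv").read_text()
    return _parse_lexicon(text)


def _parse_lexicon(text: str) -> tuple[tuple[str, FunctionalCategory], ...]:
    rules = []
    for i, line in enumerate(text.strip().splitlines()):
        if i == 0 and line.lower().startswith("keyword"):
            continue
        keyword, category = line.rstrip("\n").split("\t")
        rules.append((keyword.lower(), FunctionalCategory(category)))
    return tuple(rules)


def load_lexicon(path) -> tuple[tuple[str, FunctionalCategory], ...]:
    """Load a user lexicon TSV (keyword, category); priority = file order."""
    with open(path) as fh:
        return _parse_lexicon(fh.read())


def map_functional_category(product: str,
                            lexicon=None) -> FunctionalCategory:
    """Map one product string to its functional category.

    Keywords apply case-insensitively in lexicon order (most specific
    first, e.g. "tail sheath" before "tail"). Unmatched products fall to
    ``hypothetical`` when empty or "hypothetical protein", else ``other``.
    """
    rules = lexicon if lexicon is not None else _default_lexicon()
    text = (product or "").lower()
    if not text.strip() or "hypothetical protein" in text:
        return FunctionalCategory.HYPOTHETICAL
    for keyword, category in rules:
        if keyword in text:
            return category
    return FunctionalCategory.OTHER


def categorize_genes(genes: list[GeneFeature], lexicon=None) -> list[GeneFeature]:
    for g in genes:
        g.category = map_functional_category(g.product, lexicon)
    return genes


def classify_morphology(genes: list[GeneFeature]) -> Morphology:
    """Tail sheath present -> myovirus; tape measure without sheath -> siphovirus."""
    cats = {g.category for g in genes}
    if FunctionalCategory.TAIL_SHEATH in cats:
        return Morphology.MYOVIRUS
    if FunctionalCategory.TAPE_MEASURE in cats:
        return Morphology.SIPHOVIRUS
    return Morphology.UNDETERMINED


def assess_inducibility(genes: list[GeneFeature]) -> InducibilityVerdict:
    """Check the five essential gene blocks of a lytic-competent prophage.

    (i) an integrase or transposase; (ii) the structural set — portal,
    head and tail each present (neck optional; tape measure and sheath
    count as tail genes); (iii) a terminase subunit; (iv) a lysis gene;
    (v) a nucleic-acid-metabolism gene. Intact iff all five are present.
    """
    cats = {g.category for g in genes}
    missing: list[str] = []
    if not cats & {FunctionalCategory.INTEGRASE, FunctionalCategory.TRANSPOSASE}:
        missing.append("integrase")
    tail_like = cats & {FunctionalCategory.TAIL, FunctionalCategory.TAIL_SHEATH,
                        FunctionalCategory.TAPE_MEASURE}
    structural_ok = (FunctionalCategory.PORTAL in cats
                     and FunctionalCategory.HEAD in cats
                     and bool(tail_like))
    if not structural_ok:
        missing.append("structural")
    if not cats & {FunctionalCategory.TERMINASE_LARGE,
                   FunctionalCategory.TERMINASE_SMALL}:
        missing.append("terminase")
    if FunctionalCategory.LYSIS not in cats:
        missing.append("lysis")
    if FunctionalCategory.NUCLEIC_ACID_METABOLISM not in cats:
        missing.append("nucleic_acid_metabolism")
    status = "intact" if not missing else "defective"
    rationale = ("all essential gene blocks present" if not missing
                 else "missing blocks: " + ", ".join(missing))
    return InducibilityVerdict(status=status, missing_blocks=missing,
                               rationale=rationale)


def annotate_prophage(region: ConsensusRegion, genes: list[GeneFeature],
                      lexicon=None) -> ProphageRecord:
    """Categorize a region's genes and attach morphology and inducibility."""
    inside = [g for g in genes
              if g.interval.genome_id == region.interval.genome_id
              and g.interval.start >= region.interval.start
              and g.interval.end <= region.interval.end]
    categorize_genes(inside, lexicon)
    return ProphageRecord(
        region=region,
        genes=inside,
        morphology=classify_morphology(inside),
        inducibility=assess_inducibility(inside),
    )
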