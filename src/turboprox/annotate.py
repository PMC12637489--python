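"""GO-keyword category tagging of the final proteome.

Tagging is deliberately operational: a protein belongs to a category when
any of the category's lower-case keywords occurs as a plain substring of
any of the protein's GO term *names*.  There is no ontology traversal —
the substring rule (e.g. "mitoch" catching mitochondrion/mitochondrial
terms) is the whole definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .fpi import ProteomeEntry, ProximalProteome
from .io import GoAnnotationMap


@dataclass(frozen=True)
class CategoryRule:
    """A category label and the keyword substrings that define it."""

    category: str
    substrings: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.substrings:
            raise ValidationError(f"rule {self.category!r} has no keywords")
        if any(s != s.lower() for s in self.substrings):
            raise ValidationError(
                f"rule {self.category!r}: keywords must be lower-case"
            )

    def matches(self, terms: Iterable[str]) -> bool:
        return any(key in term for term in terms for key in self.substrings)


def default_rules() -> list[CategoryRule]:
    """The stock reporting categories.

    Phosphatase-related, protein quality control, nuclear import and
    mitochondria, plus a cell-division category (keyword set configurable;
    the default catches "cell division" and mitotic terms).
    """
    return [
        CategoryRule("phosphatase", ("dephosphorylation",)),
        CategoryRule(
            "quality_control", ("proteasome", "ubiquitin", "protein folding")
        ),
        CategoryRule("nuclear_import", ("import into nucleus",)),
        CategoryRule("mitochondria", ("mitoch",)),
        CategoryRule("cell_division", ("cell division", "mitotic")),
    ]


def tag_proteome(
    proteome: ProximalProteome,
    go_map: GoAnnotationMap,
    rules: Sequence[CategoryRule] | None = None,
) -> ProximalProteome:
    """Attach category tags to every proteome entry.

    Existing tags (bait flag, FP-list flags) are preserved; category tags
    are appended in rule order without duplicates, so tagging is
    idempotent and adding a rule never removes a tag.  Proteins absent
    from ``go_map`` simply receive no category tags.
    """
    if rules is None:
        rules = default_rules()
    entries = []
    for entry in proteome.entries:
        terms = go_map.terms(entry.accession)
        tags = list(entry.tags)
        for rule in rules:
            if rule.category not in tags and rule.matches(terms):
                tags.append(rule.category)
        entries.append(
            ProteomeEntry(
                accession=entry.accession,
                gene_symbol=entry.gene_symbol,
                ratios=dict(entry.ratios),
                mean_enrichment=entry.mean_enrichment,
                rank=entry.rank,
                tags=tags,
            )
        )
    return ProximalProteome(entries=entries, provenance=dict(proteome.provenance))


def category_counts(
    proteome: ProximalProteome, rules: Sequence[CategoryRule] | None = None
) -> dict[str, int]:
    """Per-category protein counts, bait excluded."""
    if rules is None:
        rules = default_rules()
    counts = {rule.category: 0 for rule in rules}
    for entry in proteome.entries:
        if "bait" in entry.tags:
            continue
        for rule in rules:
            if rule.category in entry.tags:
                counts[rule.category] += 1
    return counts
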