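"""Tag a proximal proteome with GO-keyword reporting categories.

Category membership is a case-insensitive substring match on GO term
names — e.g. the keyword "mitoch" catches both "mitochondrion" and
"mitochondrial translation".
"""

from turboprox import (
    GoAnnotationMap,
    category_counts,
    default_rules,
    tag_proteome,
)
from turboprox.fpi import ProteomeEntry, ProximalProteome
from turboprox.io import AXES, REPLICATES

go_map = GoAnnotationMap(
    entries={
        "P1": ["protein dephosphorylation", "nucleoplasm"],
        "P2": ["proteasome core complex", "ubiquitin binding"],
        "P3": ["protein import into nucleus"],
        "P4": ["mitochondrion organization"],
        "P5": ["mitotic spindle assembly"],
        "P6": ["rna splicing"],
    }
)

entries = [
    ProteomeEntry(
        accession=f"P{i}",
        gene_symbol=f"gene{i}",
        ratios={(axis, rep): 0.0 for axis in AXES for rep in REPLICATES},
        mean_enrichment=float(6 - i),
        rank=i,
        tags=[],
    )
    for i in range(1, 7)
]
proteome = ProximalProteome(entries=entries, provenance={})

tagged = tag_proteome(proteome, go_map, default_rules())
for entry in tagged.entries:
    print(f"{entry.accession}: {', '.join(entry.tags) or '(untagged)'}")
print("category counts:", category_counts(tagged))
# P6 stays untagged: none of its GO term names contains a rule keyword.
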