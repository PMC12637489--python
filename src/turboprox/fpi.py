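"""Empirical false-positive-rate (FPI) cutoffs and proteome assembly.

The central idea: proteins from compartments the bait cannot reach (ER
membrane, cell membrane for a nuclear bait) *should not* look enriched, so
the fraction of such proteins exceeding a candidate log2-ratio cutoff —
the False Positive Identification rate — measures how permissive that
cutoff is.  The working cutoff is the smallest observed false-positive
ratio value at which the FPI rate drops to the target (0.03 on the
no-ligase axis, 0.05 on the spatial-control axis by default).  Exceedance
is strict (ratio > cutoff) throughout, so the guarantee
``achieved_fpi <= target`` holds for every input, ties included.

A replicate's survivors are the proteins passing both filters; the final
proximal proteome is the intersection of the two replicates' survivor
sets, ranked by mean spatial-control enrichment.  False-positive-list
proteins are calibrators, not a blacklist: one that genuinely exceeds both
cutoffs stays in the list and is flagged in its tags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .enrichment import EnrichmentTable
from .errors import ValidationError
from .io import AXES, REPLICATES, CompartmentList

logger = logging.getLogger(__name__)

#: Key type for the four (axis, replicate) combinations.
AxisRep = tuple[str, str]

FILTER_AXES: dict[str, str] = {
    "filter1": "vs_no_ligase",
    "filter2": "vs_spatial_control",
}


@dataclass(frozen=True)
class FpiCurve:
    """FPI rate as a function of candidate log2-ratio cutoff.

    ``points`` holds (cutoff, fpi) pairs at every distinct observed
    false-positive-list ratio, sorted by cutoff; the fpi values are
    non-increasing and reach 0 at the largest observed ratio.
    """

    fp_list_name: str
    axis: str
    replicate: str
    points: tuple[tuple[float, float], ...]
    n_fp_observed: int


@dataclass(frozen=True)
class CutoffResult:
    """The chosen log2-ratio cutoff for one filter/replicate.

    ``achieved_fpi = n_fp_above / n_fp_observed <= target_fpi`` always.
    """

    cutoff: float
    target_fpi: float
    achieved_fpi: float
    n_fp_above: int
    fp_list_name: str = ""
    axis: str = ""
    replicate: str = ""


@dataclass
class ProteomeEntry:
    """One protein of the final proximal proteome."""

    accession: str
    gene_symbol: str
    ratios: dict[AxisRep, float]
    mean_enrichment: float
    rank: int
    tags: list[str] = field(default_factory=list)


@dataclass
class ProximalProteome:
    """The filtered, replicate-intersected, ranked protein list."""

    entries: list[ProteomeEntry]
    provenance: dict

    def __len__(self) -> int:
        return len(self.entries)

    def accessions(self) -> list[str]:
        return [e.accession for e in self.entries]


def fpi_curve(ratios: EnrichmentTable, fp_list: CompartmentList) -> FpiCurve:
    """FPI rate at every distinct observed false-positive ratio.

    For each candidate cutoff ``c`` (the sorted distinct ratios of
    FP-list proteins present in the table),

        fpi(c) = |{p in FP ∩ table : ratio(p) > c}| / |FP ∩ table|.

    Raises
    ------
    ValidationError
        No FP-list protein is present in the enrichment table.
    """
    fp_values = sorted(
        ratios.values[a] for a in fp_list.accessions if a in ratios.values
    )
    n = len(fp_values)
    if n == 0:
        raise ValidationError(
            f"no protein of FP list {fp_list.name!r} found in the "
            f"{ratios.axis}/{ratios.replicate} enrichment table"
        )
    points = []
    for cutoff in sorted(set(fp_values)):
        n_above = sum(1 for v in fp_values if v > cutoff)
        points.append((cutoff, n_above / n))
    return FpiCurve(
        fp_list_name=fp_list.name,
        axis=ratios.axis,
        replicate=ratios.replicate,
        points=tuple(points),
        n_fp_observed=n,
    )


def cutoff_at_fpi(curve: FpiCurve, target: float) -> CutoffResult:
    """Smallest candidate cutoff whose FPI rate does not exceed ``target``.

    Equivalently, with ``n`` observed FP proteins and ``k = floor(target·n)``
    allowed exceedances, the cutoff is the (n−k)-th smallest FP ratio; ties
    collapse toward fewer exceedances, so ``achieved_fpi <= target`` holds
    unconditionally.

    Raises
    ------
    ValidationError
        ``target`` outside the open interval (0, 1).
    """
    if not 0 < target < 1:
        raise ValidationError(f"target FPI must be in (0, 1), got {target}")
    for cutoff, fpi in curve.points:  # ascending cutoff, fpi non-increasing
        if fpi <= target:
            return CutoffResult(
                cutoff=cutoff,
                target_fpi=target,
                achieved_fpi=fpi,
                n_fp_above=round(fpi * curve.n_fp_observed),
                fp_list_name=curve.fp_list_name,
                axis=curve.axis,
                replicate=curve.replicate,
            )
    raise AssertionError("unreachable: fpi at the maximal cutoff is 0")


def apply_filter(ratios: EnrichmentTable, cutoff: CutoffResult) -> set[str]:
    """Accessions whose ratio strictly exceeds the cutoff."""
    return {a for a, v in ratios.values.items() if v > cutoff.cutoff}


def fold_reduction(before: int, after: int) -> float:
    """How many-fold the filters shrank the candidate list."""
    if before < 0 or after < 0:
        raise ValidationError("counts must be non-negative")
    if after == 0:
        logger.warning("fold_reduction: empty final list, reporting inf")
        return math.inf
    return before / after


def build_proteome(
    pass_sets: Mapping[AxisRep, set[str]],
    ratios: Mapping[AxisRep, EnrichmentTable],
    bait: str,
    *,
    fp_lists: Sequence[CompartmentList] = (),
    provenance: dict | None = None,
    gene_symbols: Mapping[str, str] | None = None,
) -> ProximalProteome:
    """Intersect per-replicate survivors into the final proximal proteome.

    A replicate's survivors are the intersection of its two filter pass
    sets; the final list is the intersection of the two replicates'
    survivors, ranked by mean log2 enrichment over the spatial control
    (descending, ties broken by accession).  The bait is kept and tagged
    ``bait`` so category summaries can exclude it; membership in a
    false-positive list is flagged as ``fp_list:<name>``.
    """
    for axis in FILTER_AXES.values():
        for rep in REPLICATES:
            if (axis, rep) not in pass_sets or (axis, rep) not in ratios:
                raise ValidationError(f"missing pass set or ratios for {(axis, rep)}")

    rep_survivors = {
        rep: pass_sets[(AXES[0], rep)] & pass_sets[(AXES[1], rep)]
        for rep in REPLICATES
    }
    final = rep_survivors["rep1"] & rep_survivors["rep2"]

    in_tables = any(bait in ratios[key].values for key in ratios)
    if not in_tables:
        logger.warning("bait %s absent from the enrichment tables", bait)

    spatial = FILTER_AXES["filter2"]
    entries = []
    for accession in final:
        entry_ratios = {
            (axis, rep): ratios[(axis, rep)].values[accession]
            for axis in AXES
            for rep in REPLICATES
        }
        mean_enrichment = (
            entry_ratios[(spatial, "rep1")] + entry_ratios[(spatial, "rep2")]
        ) / 2.0
        tags = []
        if accession == bait:
            tags.append("bait")
        for fp_list in fp_lists:
            if accession in fp_list.accessions:
                tags.append(f"fp_list:{fp_list.name}")
        symbol = (gene_symbols or {}).get(accession, "")
        entries.append(
            ProteomeEntry(
                accession=accession,
                gene_symbol=symbol,
                ratios=entry_ratios,
                mean_enrichment=mean_enrichment,
                rank=0,
                tags=tags,
            )
        )
    entries.sort(key=lambda e: (-e.mean_enrichment, e.accession))
    for i, entry in enumerate(entries, start=1):
        entry.rank = i
    logger.info(
        "proteome: rep1 %d survivors, rep2 %d survivors, final %d",
        len(rep_survivors["rep1"]),
        len(rep_survivors["rep2"]),
        len(entries),
    )
    return ProximalProteome(entries=entries, provenance=provenance or {})
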