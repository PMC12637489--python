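"""From raw reporter intensities to per-protein log2 enrichment ratios.

The pipeline's two filter axes are ratios of a bait-replicate channel over
the no-ligase control (removes endogenous-biotin/bead background) and over
the nuclear spatial control (removes compartment-generic labeling).
Channels are median-equalized first — channel loading is nominally equal,
so residual median differences are technical — and proteins with a zero
intensity in either channel of a ratio are dropped and counted, never
imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io import ProteinQuantRecord

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTable:
    """Per-protein log2 ratios for one (axis, replicate) pair.

    ``n_dropped`` counts proteins excluded because either channel intensity
    was zero (log2 undefined), so ``len(values) + n_dropped`` equals the
    number of input proteins.
    """

    axis: str
    replicate: str
    values: dict[str, float]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CorrelationReport:
    """OLS fit of one replicate's ratios on the other's.

    ``r_squared`` is the squared Pearson correlation over the shared
    proteins; ``slope``/``intercept`` describe the fitted line b ≈
    slope·a + intercept.
    """

    r_squared: float
    slope: float
    intercept: float
    n: int


def filter_by_peptides(
    records: Sequence[ProteinQuantRecord], min_unique: int = 2
) -> list[ProteinQuantRecord]:
    """Keep proteins identified by *more than* ``min_unique`` peptides.

    The comparison is strict: with the default of 2, a protein needs at
    least 3 unique peptides to survive.  Order is preserved.
    """
    if min_unique < 0:
        raise ValidationError("min_unique must be >= 0")
    kept = [r for r in records if r.unique_peptides > min_unique]
    logger.info(
        "peptide filter (>%d unique): %d of %d proteins kept",
        min_unique,
        len(kept),
        len(records),
    )
    return kept


def normalize_channels(
    records: Sequence[ProteinQuantRecord],
) -> list[ProteinQuantRecord]:
    """Equalize channel medians.

    Each channel's intensities are divided by that channel's median
    positive intensity and multiplied by the median of the per-channel
    medians, so all channel medians end up equal and the overall scale is
    preserved.  Zeros stay zero.  The operation is idempotent.

    Raises
    ------
    ValidationError
        A channel has no positive intensity.
    """
    if not records:
        return []
    channels = list(records[0].intensities)
    medians: dict[str, float] = {}
    for channel in channels:
        positive = [
            r.intensities[channel]
            for r in records
            if r.intensities[channel] > 0
        ]
        if not positive:
            raise ValidationError(
                f"channel {channel} has no positive intensity"
            )
        medians[channel] = float(np.median(positive))
    grand = float(np.median(list(medians.values())))
    scale = {c: grand / medians[c] for c in channels}
    return [
        ProteinQuantRecord(
            accession=r.accession,
            gene_symbol=r.gene_symbol,
            unique_peptides=r.unique_peptides,
            intensities={c: r.intensities[c] * scale[c] for c in channels},
        )
        for r in records
    ]


def log2_ratio(
    records: Sequence[ProteinQuantRecord],
    numerator: str,
    denominator: str,
    *,
    axis: str,
    replicate: str,
) -> EnrichmentTable:
    """Per-protein ``log2(numerator / denominator)`` reporter-ion ratios.

    Proteins with zero intensity in either channel are dropped (the ratio
    is undefined) and tallied in ``n_dropped``.
    """
    if records:
        for channel in (numerator, denominator):
            if channel not in records[0].intensities:
                raise ValidationError(f"unknown channel {channel!r}")
    values: dict[str, float] = {}
    n_dropped = 0
    for r in records:
        num = r.intensities[numerator]
        den = r.intensities[denominator]
        if num == 0 or den == 0:
            n_dropped += 1
            logger.debug(
                "dropping %s from %s/%s: zero intensity", r.accession, axis, replicate
            )
            continue
        values[r.accession] = math.log2(num / den)
    if n_dropped:
        logger.info(
            "%s/%s: dropped %d protein(s) with zero intensity",
            axis,
            replicate,
            n_dropped,
        )
    return EnrichmentTable(
        axis=axis, replicate=replicate, values=values, n_dropped=n_dropped
    )


def replicate_correlation(
    a: EnrichmentTable, b: EnrichmentTable
) -> CorrelationReport:
    """OLS fit of ``b`` on ``a`` over their shared accessions.

    This is the replicate-agreement QC: two independent bait experiments
    should give strongly correlated enrichment ratios (high R²).

    Raises
    ------
    ValidationError
        Fewer than two shared proteins, or zero variance in ``a``.
    """
    shared = sorted(set(a.values) & set(b.values))
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} shared protein(s); need at least 2"
        )
    x = np.array([a.values[acc] for acc in shared])
    y = np.array([b.values[acc] for acc in shared])
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in first table; fit undefined")
    fit = stats.linregress(x, y)
    return CorrelationReport(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(shared),
    )
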