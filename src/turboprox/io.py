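"""Reading and writing of every external table the pipeline touches.

All files are delimited text (tab by default, comma via ``delimiter=","``):
protein-level TMT quantification tables, compartment false-positive lists
(one UniProt accession per line), accession→GO-term-name maps, and the
final proximal-proteome result table.  No binary mass-spectrometry formats
are handled — upstream peptide identification and quantification are out
of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: The four channel roles of the 4-plex design.
CHANNEL_ROLES = ("no_ligase", "spatial_control", "bait_rep1", "bait_rep2")

#: Default TMT channel labels for each role (no-ligase control in 134N,
#: nuclear spatial control in 133C, the two bait replicates in 133N/126C).
DEFAULT_CHANNEL_ROLES: dict[str, str] = {
    "no_ligase": "134N",
    "spatial_control": "133C",
    "bait_rep1": "133N",
    "bait_rep2": "126C",
}

#: Enrichment axes: bait replicate over the no-ligase control (filter 1)
#: and over the nuclear spatial control (filter 2).
AXES = ("vs_no_ligase", "vs_spatial_control")
REPLICATES = ("rep1", "rep2")


@dataclass
class ProteinQuantRecord:
    """One protein's identity, evidence and per-channel reporter intensities.

    Parameters
    ----------
    accession
        Protein identifier, unique within a table.
    gene_symbol
        Display name; may be empty.
    unique_peptides
        Number of distinct peptide sequences supporting the identification.
    intensities
        Mapping channel label → reporter intensity (non-negative, arbitrary
        units).  Every record in a table carries the same channel labels.
    """

    accession: str
    gene_symbol: str
    unique_peptides: int
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        if self.unique_peptides < 0:
            raise ValidationError(
                f"{self.accession}: unique_peptides must be >= 0"
            )
        for channel, value in self.intensities.items():
            if value < 0:
                raise ValidationError(
                    f"{self.accession}: negative intensity in channel {channel}"
                )


@dataclass(frozen=True)
class CompartmentList:
    """A named set of accessions from an irrelevant subcellular compartment.

    These proteins should not be proximal to a nuclear bait; the fraction of
    them exceeding a candidate cutoff defines the FPI rate.
    """

    name: str
    accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValidationError(f"compartment list {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class GoAnnotationMap:
    """Accession → list of lower-cased GO term names."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def terms(self, accession: str) -> list[str]:
        """Term names for ``accession``; empty list when unmapped."""
        return self.entries.get(accession, [])


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty or has no header") from exc


def read_quant_table(
    path: str | Path,
    channel_roles: Mapping[str, str] | None = None,
    *,
    delimiter: str = "\t",
    accession_column: str = "accession",
    gene_symbol_column: str = "gene_symbol",
    peptides_column: str = "unique_peptides",
) -> list[ProteinQuantRecord]:
    """Read a protein-level TMT quantification table.

    The table must name an accession column, a gene-symbol column, a
    unique-peptide-count column and one intensity column per channel label.
    Column names are configurable because supplementary-table schemas vary
    between labs.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    channel_roles
        Mapping role → channel label; all four roles (``no_ligase``,
        ``spatial_control``, ``bait_rep1``, ``bait_rep2``) must map to
        existing columns.  Defaults to :data:`DEFAULT_CHANNEL_ROLES`.

    Returns
    -------
    list of ProteinQuantRecord, one per data row, row order preserved.

    Raises
    ------
    FormatError
        A required column is missing (named in the message).
    ParseError
        A non-numeric or negative value, with its row number.
    ValidationError
        Duplicate accessions.
    """
    roles = dict(channel_roles or DEFAULT_CHANNEL_ROLES)
    missing_roles = [r for r in CHANNEL_ROLES if r not in roles]
    if missing_roles:
        raise FormatError(f"channel_roles missing role(s): {missing_roles}")

    frame = _read_table(path, delimiter)
    for column in (accession_column, gene_symbol_column, peptides_column):
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    channel_labels = [roles[r] for r in CHANNEL_ROLES]
    for label in channel_labels:
        if label not in frame.columns:
            raise FormatError(f"{path}: missing mapped channel column {label!r}")
    # the table may carry extra channels beyond the four mapped roles
    extra = [
        c
        for c in frame.columns
        if c
        not in {accession_column, gene_symbol_column, peptides_column}
        and c not in channel_labels
    ]
    all_channels = channel_labels + extra

    records: list[ProteinQuantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row_map = dict(zip(frame.columns, row))
        accession = row_map[accession_column].strip()
        if not accession:
            raise ParseError(f"{path}: row {i}: empty accession")
        if accession in seen:
            raise ValidationError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        try:
            peptides = int(row_map[peptides_column])
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {i}: non-integer unique_peptides "
                f"{row_map[peptides_column]!r}"
            ) from exc
        intensities: dict[str, float] = {}
        for channel in all_channels:
            raw = row_map[channel]
            try:
                value = float(raw)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: row {i}: non-numeric intensity {raw!r} "
                    f"in channel {channel}"
                ) from exc
            if value < 0:
                raise ParseError(
                    f"{path}: row {i}: negative intensity {value} "
                    f"in channel {channel}"
                )
            intensities[channel] = value
        try:
            records.append(
                ProteinQuantRecord(
                    accession=accession,
                    gene_symbol=row_map[gene_symbol_column],
                    unique_peptides=peptides,
                    intensities=intensities,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    logger.info("read %d protein records from %s", len(records), path)
    return records


def write_quant_table(
    records: Sequence[ProteinQuantRecord],
    path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    """Write records back to delimited text (inverse of :func:`read_quant_table`)."""
    if not records:
        raise ValidationError("cannot write an empty quantification table")
    channels = list(records[0].intensities)
    rows = [
        {
            "accession": r.accession,
            "gene_symbol": r.gene_symbol,
            "unique_peptides": r.unique_peptides,
            **{c: repr(float(r.intensities[c])) for c in channels},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_compartment_list(
    path: str | Path, name: str
) -> CompartmentList:
    """Read a false-positive compartment list: one accession per line.

    Blank lines and ``#`` comments are ignored; duplicate accessions are
    collapsed with a logged warning.

    Raises
    ------
    ValidationError
        No accessions remain after parsing.
    """
    accessions: list[str] = []
    with open(path) as handle:
        for line in handle:
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            accessions.append(entry)
    unique = set(accessions)
    n_dup = len(accessions) - len(unique)
    if n_dup:
        logger.warning(
            "compartment list %s (%s): %d duplicate line(s) collapsed",
            name,
            path,
            n_dup,
        )
    if not unique:
        raise ValidationError(f"{path}: compartment list {name!r} is empty")
    return CompartmentList(name=name, accessions=frozenset(unique))


def write_compartment_list(comp: CompartmentList, path: str | Path) -> None:
    """Write a compartment list, one accession per line, sorted."""
    with open(path, "w") as handle:
        handle.write(f"# {comp.name}\n")
        for accession in sorted(comp.accessions):
            handle.write(accession + "\n")


def read_go_map(path: str | Path, *, delimiter: str = "\t") -> GoAnnotationMap:
    """Read a two-column (accession, GO term name) file into a map.

    Multiple rows per accession accumulate; term names are lower-cased
    because category matching is case-insensitive.  An empty file yields an
    empty map.

    Raises
    ------
    ParseError
        A row with a field count other than two, with its row number.
    """
    entries: dict[str, list[str]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: row {i}: expected 2 fields, got {len(fields)}"
                )
            accession, term = fields
            entries.setdefault(accession.strip(), []).append(
                term.strip().lower()
            )
    return GoAnnotationMap(entries=entries)


# ---------------------------------------------------------------------------
# proximal-proteome result table

_PROTEOME_RATIO_COLUMNS = [
    f"log2_{axis}_{rep}" for axis in AXES for rep in REPLICATES
]


def write_proteome_table(proteome, path: str | Path, *, delimiter: str = "\t") -> None:
    """Materialize a ranked :class:`~turboprox.fpi.ProximalProteome` as text.

    Columns: accession, gene_symbol, the four log2 ratios (two filter axes ×
    two replicates), mean enrichment, rank, and semicolon-joined category
    tags.  Output is bit-stable for a fixed proteome.
    """
    with open(path, "w") as handle:
        header = (
            ["accession", "gene_symbol"]
            + _PROTEOME_RATIO_COLUMNS
            + ["mean_enrichment", "rank", "tags"]
        )
        handle.write(delimiter.join(header) + "\n")
        for entry in proteome.entries:
            cells = [entry.accession, entry.gene_symbol]
            for axis in AXES:
                for rep in REPLICATES:
                    cells.append(repr(entry.ratios[(axis, rep)]))
            cells.append(repr(entry.mean_enrichment))
            cells.append(str(entry.rank))
            cells.append(";".join(entry.tags))
            handle.write(delimiter.join(cells) + "\n")


def read_proteome_table(path: str | Path, *, delimiter: str = "\t"):
    """Read back a table written by :func:`write_proteome_table`."""
    from .fpi import ProteomeEntry, ProximalProteome

    frame = _read_table(path, delimiter)
    expected = (
        ["accession", "gene_symbol"]
        + _PROTEOME_RATIO_COLUMNS
        + ["mean_enrichment", "rank", "tags"]
    )
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: unexpected proteome table header")
    entries = []
    for row in frame.itertuples(index=False):
        row_map = dict(zip(frame.columns, row))
        ratios = {
            (axis, rep): float(row_map[f"log2_{axis}_{rep}"])
            for axis in AXES
            for rep in REPLICATES
        }
        entries.append(
            ProteomeEntry(
                accession=row_map["accession"],
                gene_symbol=row_map["gene_symbol"],
                ratios=ratios,
                mean_enrichment=float(row_map["mean_enrichment"]),
                rank=int(row_map["rank"]),
                tags=[t for t in row_map["tags"].split(";") if t],
            )
        )
    return ProximalProteome(entries=entries, provenance={})
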