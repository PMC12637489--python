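"""End-to-end orchestration: read → filter → ratio → cutoff → intersect → report.

`run_pipeline` executes the stages in a fixed order and writes every
result as delimited text plus QC plots, together with a manifest (config,
package version, input checksums) sufficient to re-run bit-identically.
All randomness lives in the simulator; the pipeline itself is
deterministic, so identical inputs give byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import category_counts, default_rules, tag_proteome
from .enrichment import (
    CorrelationReport,
    filter_by_peptides,
    log2_ratio,
    normalize_channels,
    replicate_correlation,
)
from .errors import ConfigError
from .fpi import (
    FILTER_AXES,
    CutoffResult,
    FpiCurve,
    ProximalProteome,
    apply_filter,
    build_proteome,
    cutoff_at_fpi,
    fold_reduction,
    fpi_curve,
)
from .io import (
    DEFAULT_CHANNEL_ROLES,
    REPLICATES,
    read_compartment_list,
    read_go_map,
    read_quant_table,
    write_proteome_table,
)

logger = logging.getLogger(__name__)

_BAIT_CHANNEL = {"rep1": "bait_rep1", "rep2": "bait_rep2"}
_DENOMINATOR = {"vs_no_ligase": "no_ligase", "vs_spatial_control": "spatial_control"}


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML with CLI overrides."""

    quant_table: str
    fp_list_er: str
    fp_list_cm: str
    bait: str
    out_dir: str
    channel_roles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )
    min_unique_peptides: int = 2
    normalize: bool = True
    fpi_target_filter1: float = 0.03
    fpi_target_filter2: float = 0.05
    go_map: str | None = None
    delimiter: str = "\t"
    correlation_axis: str = "vs_no_ligase"

    def validate(self) -> None:
        for target, name in (
            (self.fpi_target_filter1, "fpi_target_filter1"),
            (self.fpi_target_filter2, "fpi_target_filter2"),
        ):
            if not 0 < target < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {target}")
        if self.fpi_target_filter1 > self.fpi_target_filter2:
            logger.warning(
                "filter-1 FPI target (%g) is looser than filter-2's (%g)",
                self.fpi_target_filter1,
                self.fpi_target_filter2,
            )
        paths = [self.quant_table, self.fp_list_er, self.fp_list_cm]
        if self.go_map:
            paths.append(self.go_map)
        for path in paths:
            if not Path(path).is_file():
                raise ConfigError(f"input file not found: {path}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class PipelineResult:
    """Outputs of one pipeline run, with provenance."""

    proteome: ProximalProteome
    correlation: CorrelationReport
    curves: dict[tuple[str, str], FpiCurve]
    cutoffs: dict[tuple[str, str], CutoffResult]
    n_quantified: int
    n_after_peptide_filter: int
    fold_reduction: float


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def execute(
    records,
    er_list,
    cm_list,
    bait: str,
    *,
    min_unique_peptides: int = 2,
    normalize: bool = True,
    fpi_target_filter1: float = 0.03,
    fpi_target_filter2: float = 0.05,
    channel_roles: dict[str, str] | None = None,
    go_map=None,
    correlation_axis: str = "vs_no_ligase",
    provenance_config: dict | None = None,
) -> tuple[PipelineResult, dict]:
    """Run the in-memory stage chain; no files are touched.

    Returns the :class:`PipelineResult` and the four enrichment tables
    keyed by (axis, replicate).  :func:`run_pipeline` wraps this with file
    I/O; call it directly when the inputs are already in memory (e.g. a
    freshly simulated experiment).
    """
    roles = dict(channel_roles or DEFAULT_CHANNEL_ROLES)
    n_quantified = len(records)
    records = filter_by_peptides(records, min_unique_peptides)
    n_filtered = len(records)
    if normalize:
        records = normalize_channels(records)

    ratios = {
        (axis, rep): log2_ratio(
            records,
            roles[_BAIT_CHANNEL[rep]],
            roles[_DENOMINATOR[axis]],
            axis=axis,
            replicate=rep,
        )
        for axis in FILTER_AXES.values()
        for rep in REPLICATES
    }

    fp_by_filter = {"filter1": er_list, "filter2": cm_list}
    target_by_filter = {
        "filter1": fpi_target_filter1,
        "filter2": fpi_target_filter2,
    }
    curves: dict[tuple[str, str], FpiCurve] = {}
    cutoffs: dict[tuple[str, str], CutoffResult] = {}
    pass_sets = {}
    for filter_name, axis in FILTER_AXES.items():
        for rep in REPLICATES:
            curve = fpi_curve(ratios[(axis, rep)], fp_by_filter[filter_name])
            cutoff = cutoff_at_fpi(curve, target_by_filter[filter_name])
            curves[(filter_name, rep)] = curve
            cutoffs[(filter_name, rep)] = cutoff
            pass_sets[(axis, rep)] = apply_filter(ratios[(axis, rep)], cutoff)
            logger.info(
                "%s %s: cutoff %.4f (achieved FPI %.4f, %d/%d FP above), "
                "%d proteins pass",
                filter_name,
                rep,
                cutoff.cutoff,
                cutoff.achieved_fpi,
                cutoff.n_fp_above,
                curve.n_fp_observed,
                len(pass_sets[(axis, rep)]),
            )

    gene_symbols = {r.accession: r.gene_symbol for r in records}
    provenance = {
        "config": provenance_config or {},
        "cutoffs": {
            f"{f}_{rep}": dataclasses.asdict(cutoffs[(f, rep)])
            for f in FILTER_AXES
            for rep in REPLICATES
        },
    }
    proteome = build_proteome(
        pass_sets,
        ratios,
        bait,
        fp_lists=(er_list, cm_list),
        provenance=provenance,
        gene_symbols=gene_symbols,
    )
    if go_map is not None:
        proteome = tag_proteome(proteome, go_map)

    correlation = replicate_correlation(
        ratios[(correlation_axis, "rep1")],
        ratios[(correlation_axis, "rep2")],
    )
    reduction = fold_reduction(n_filtered, len(proteome))

    result = PipelineResult(
        proteome=proteome,
        correlation=correlation,
        curves=curves,
        cutoffs=cutoffs,
        n_quantified=n_quantified,
        n_after_peptide_filter=n_filtered,
        fold_reduction=reduction,
    )
    return result, ratios


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read the inputs, run every stage and write outputs to ``out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = read_quant_table(
        config.quant_table,
        config.channel_roles,
        delimiter=config.delimiter,
    )
    er_list = read_compartment_list(config.fp_list_er, "ER_membrane")
    cm_list = read_compartment_list(config.fp_list_cm, "cell_membrane")
    go_map = read_go_map(config.go_map) if config.go_map else None

    result, ratios = execute(
        records,
        er_list,
        cm_list,
        config.bait,
        min_unique_peptides=config.min_unique_peptides,
        normalize=config.normalize,
        fpi_target_filter1=config.fpi_target_filter1,
        fpi_target_filter2=config.fpi_target_filter2,
        channel_roles=config.channel_roles,
        go_map=go_map,
        correlation_axis=config.correlation_axis,
        provenance_config=dataclasses.asdict(config),
    )
    _write_outputs(config, result, ratios, out_dir)
    return result


def _write_outputs(config, result, ratios, out_dir: Path) -> None:
    write_proteome_table(
        result.proteome, out_dir / "proteome.tsv", delimiter=config.delimiter
    )
    for (filter_name, rep), curve in result.curves.items():
        with open(out_dir / f"fpi_curve_{filter_name}_{rep}.tsv", "w") as handle:
            handle.write("cutoff\tfpi\n")
            for cutoff, fpi_value in curve.points:
                handle.write(f"{cutoff!r}\t{fpi_value!r}\n")
    with open(out_dir / "cutoffs.tsv", "w") as handle:
        handle.write(
            "filter\treplicate\taxis\tfp_list\tcutoff\ttarget_fpi\t"
            "achieved_fpi\tn_fp_above\tn_fp_observed\n"
        )
        for (filter_name, rep), cut in result.cutoffs.items():
            curve = result.curves[(filter_name, rep)]
            handle.write(
                f"{filter_name}\t{rep}\t{cut.axis}\t{cut.fp_list_name}\t"
                f"{cut.cutoff!r}\t{cut.target_fpi}\t{cut.achieved_fpi!r}\t"
                f"{cut.n_fp_above}\t{curve.n_fp_observed}\n"
            )

    manifest = {
        "package": "turboprox",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("quant_table", config.quant_table),
                ("fp_list_er", config.fp_list_er),
                ("fp_list_cm", config.fp_list_cm),
            )
        }
        | ({"go_map": _sha256(config.go_map)} if config.go_map else {}),
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")

    write_summary(result, out_dir / "summary.txt")
    try:
        write_plots(result, ratios, out_dir)
    except Exception:  # plots are best-effort; tables are the record
        logger.exception("plotting failed; tables were still written")


def write_summary(result: PipelineResult, path: str | Path) -> None:
    """Human-readable run summary."""
    lines = [
        "turboprox run summary",
        "=====================",
        f"proteins quantified:          {result.n_quantified}",
        f"after unique-peptide filter:  {result.n_after_peptide_filter}",
        f"final proximal proteome:      {len(result.proteome)}",
        f"fold reduction:               {result.fold_reduction:.1f}",
        "",
        (
            "replicate correlation: "
            f"R^2 = {result.correlation.r_squared:.3f}, "
            f"slope = {result.correlation.slope:.3f}, "
            f"intercept = {result.correlation.intercept:.3f}, "
            f"n = {result.correlation.n}"
        ),
        "",
        "cutoffs:",
    ]
    for (filter_name, rep), cut in sorted(result.cutoffs.items()):
        lines.append(
            f"  {filter_name} {rep} ({cut.axis}, FP list {cut.fp_list_name}): "
            f"log2 cutoff {cut.cutoff:.3f} at target FPI {cut.target_fpi} "
            f"(achieved {cut.achieved_fpi:.4f}, {cut.n_fp_above} above)"
        )
    if result.proteome.entries:
        top = result.proteome.entries[0]
        lines += [
            "",
            (
                f"most enriched: {top.accession} "
                f"(mean log2 enrichment {top.mean_enrichment:.2f})"
            ),
        ]
        counts = category_counts(result.proteome)
        if any(counts.values()):
            lines.append("category counts (bait excluded):")
            for category, count in counts.items():
                lines.append(f"  {category}: {count}")
    else:
        lines.append("")
        lines.append("no proteins passed both filters in both replicates")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def write_plots(result: PipelineResult, ratios, out_dir: Path) -> None:
    """QC figures: replicate scatter, FPI curves, filter-vs-filter scatters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # replicate agreement with OLS line and R^2 annotation
    axis = result.proteome.provenance.get("config", {}).get(
        "correlation_axis", "vs_no_ligase"
    )
    a, b = ratios[(axis, "rep1")], ratios[(axis, "rep2")]
    shared = sorted(set(a.values) & set(b.values))
    x = [a.values[acc] for acc in shared]
    y = [b.values[acc] for acc in shared]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=4, alpha=0.4, color="#444444")
    corr = result.correlation
    if x:
        lo, hi = min(x), max(x)
        ax.plot(
            [lo, hi],
            [corr.slope * lo + corr.intercept, corr.slope * hi + corr.intercept],
            color="crimson",
        )
    ax.annotate(
        f"$R^2$ = {corr.r_squared:.3f}", xy=(0.05, 0.92), xycoords="axes fraction"
    )
    ax.set_xlabel(f"replicate 1 log2 ratio ({axis})")
    ax.set_ylabel(f"replicate 2 log2 ratio ({axis})")
    fig.savefig(out_dir / "replicate_scatter.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    # FPI curves with the chosen cutoff marked
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for ax_, ((filter_name, rep), curve) in zip(
        axes.ravel(), sorted(result.curves.items())
    ):
        xs = [p[0] for p in curve.points]
        ys = [p[1] for p in curve.points]
        cut = result.cutoffs[(filter_name, rep)]
        ax_.step(xs, ys, where="post", color="#2a6f97")
        ax_.axvline(cut.cutoff, color="crimson", linestyle="--")
        ax_.axhline(cut.target_fpi, color="gray", linestyle=":")
        ax_.set_title(
            f"{filter_name} {rep}: cutoff {cut.cutoff:.3f} @ FPI {cut.target_fpi}"
        )
        ax_.set_xlabel(f"log2 ratio ({curve.axis})")
        ax_.set_ylabel("FPI rate")
    fig.tight_layout()
    fig.savefig(out_dir / "fpi_curves.png", dpi=120)
    plt.close(fig)

    # filter-1 vs filter-2 scatter per replicate, cutoff lines drawn
    final = set(result.proteome.accessions())
    for rep in REPLICATES:
        t1 = ratios[(FILTER_AXES["filter1"], rep)]
        t2 = ratios[(FILTER_AXES["filter2"], rep)]
        shared = sorted(set(t1.values) & set(t2.values))
        xs = [t1.values[acc] for acc in shared]
        ys = [t2.values[acc] for acc in shared]
        colors = ["crimson" if acc in final else "#999999" for acc in shared]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(xs, ys, s=4, alpha=0.5, c=colors)
        ax.axvline(result.cutoffs[("filter1", rep)].cutoff, color="k", linestyle="--")
        ax.axhline(result.cutoffs[("filter2", rep)].cutoff, color="k", linestyle="--")
        ax.set_xlabel("log2 ratio vs no-ligase (filter 1)")
        ax.set_ylabel("log2 ratio vs spatial control (filter 2)")
        ax.set_title(f"{rep}: final proteome in red")
        fig.savefig(out_dir / f"filter_scatter_{rep}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
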