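"""Synthetic 4-plex TMT proximity-labeling experiments with known truth.

The generator emulates a TurboID design with four reporter channels: a
no-ligase control (endogenously biotinylated proteins and bead binders
only), a nuclear spatial control (TurboID-NLS, labeling the shared nuclear
background), and two independent bait replicates.  Each simulated protein
belongs to one of six classes:

``bait``
    the ligase-fusion protein itself; strongest self-labeling.
``true_proximal``
    genuinely proximal to the bait; enriched in bait channels over the
    spatial control by ``bait_effect`` log2 units.
``background``
    nuclear proteins labeled equally by the bait and the spatial control.
``er_fp`` / ``cm_fp``
    ER-membrane / cell-membrane proteins.  Their channel-effect profile is
    deliberately identical to ``background`` (exchangeable ratio
    distributions), which is what makes them usable as false-positive
    reference populations for cutoff calibration.
``contaminant``
    endogenous-biotin and bead binders, elevated equally in *every*
    channel including no-ligase — so the no-ligase filter axis is what
    removes them.

Log2 reporter intensities are Gaussian (intensities log-normal): per
protein ``i`` and channel ``c``,

    log2 I[i, c] = b_i + E(class_i, c) + d_i[c] + eps[i, c]

with ``b_i ~ N(base_log_intensity, base_sd)`` the protein's abundance,
``E`` the class/channel effect matrix, ``d_i`` per-protein effect
deviations applied to the two bait channels (bivariate normal, sd
``effect_sd``, correlation ``replicate_rho``) and ``eps`` i.i.d. channel
noise with sd ``noise_sd``.  A fixed seed gives bit-identical output.

Draw order (reproducibility contract): one ``numpy.random.default_rng``
stream; (1) abundances ``b`` for all proteins, (2) replicate-deviation
pairs, (3) the n×4 channel-noise matrix in role order no-ligase, spatial
control, bait rep1, bait rep2, (4) unique-peptide counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ValidationError
from .io import (
    AXES,
    CHANNEL_ROLES,
    DEFAULT_CHANNEL_ROLES,
    CompartmentList,
    ProteinQuantRecord,
)

CLASSES = (
    "bait",
    "true_proximal",
    "background",
    "er_fp",
    "cm_fp",
    "contaminant",
)

ClassLabel = Literal[
    "bait", "true_proximal", "background", "er_fp", "cm_fp", "contaminant"
]

BAIT_ACCESSION = "BAIT0001"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic 4-plex experiment.

    Class sizes default to a realistically background-dominated nuclear
    proteome (2000 background proteins, 25 true proximal, 150 proteins in
    each false-positive compartment list, 50 contaminants).  Effects are in
    log2 units: ``bait_vs_noligase_effect`` is how much *any* labeled
    protein gains in a ligase-containing channel over the no-ligase
    control, ``bait_effect`` the additional gain of a true proximal protein
    in the bait channels over the spatial control.
    """

    n_background: int = 2000
    n_true_proximal: int = 25
    n_er_fp: int = 150
    n_cm_fp: int = 150
    n_contaminant: int = 50
    bait_effect: float = 2.0
    bait_vs_noligase_effect: float = 3.0
    noise_sd: float = 0.5
    replicate_rho: float = 0.9
    base_log_intensity: float = 16.0
    peptide_lambda: float = 8.0
    seed: int = 7
    # spread parameters of the generative model
    effect_sd: float = 0.2
    base_sd: float = 2.0
    contaminant_effect: float = 3.0
    bait_self_factor: float = 2.0
    channel_roles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )

    def __post_init__(self) -> None:
        for name in (
            "n_background",
            "n_true_proximal",
            "n_er_fp",
            "n_cm_fp",
            "n_contaminant",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if abs(self.replicate_rho) > 1:
            raise ValidationError("replicate_rho must lie in [-1, 1]")
        if self.effect_sd < 0:
            raise ValidationError("effect_sd must be >= 0")
        if self.peptide_lambda < 1:
            raise ValidationError("peptide_lambda must be >= 1")
        missing = [r for r in CHANNEL_ROLES if r not in self.channel_roles]
        if missing:
            raise ValidationError(f"channel_roles missing {missing}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        """A copy of this config with a different RNG seed."""
        return replace(self, seed=seed)

    @property
    def n_proteins(self) -> int:
        """Total simulated proteins including the bait."""
        return (
            1
            + self.n_true_proximal
            + self.n_background
            + self.n_er_fp
            + self.n_cm_fp
            + self.n_contaminant
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth class label for every simulated accession."""

    labels: dict[str, str]

    def accessions_of(self, cls: str) -> set[str]:
        return {a for a, c in self.labels.items() if c == cls}


def _effect_matrix(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Mean log2 effect per (class, channel role)."""
    v = config.bait_vs_noligase_effect
    be = config.bait_effect
    ce = config.contaminant_effect
    labeled_bg = {
        "no_ligase": 0.0,
        "spatial_control": v,
        "bait_rep1": v,
        "bait_rep2": v,
    }
    return {
        "background": dict(labeled_bg),
        "er_fp": dict(labeled_bg),
        "cm_fp": dict(labeled_bg),
        "true_proximal": {
            "no_ligase": 0.0,
            "spatial_control": v,
            "bait_rep1": v + be,
            "bait_rep2": v + be,
        },
        "bait": {
            "no_ligase": 0.0,
            "spatial_control": v,
            "bait_rep1": v + config.bait_self_factor * be,
            "bait_rep2": v + config.bait_self_factor * be,
        },
        "contaminant": {role: ce for role in CHANNEL_ROLES},
    }


def expected_ratio(config: SimulationConfig, cls: str, axis: str) -> float:
    """Noise-free mean log2 ratio implied by the generative model.

    ``axis`` is ``vs_no_ligase`` or ``vs_spatial_control``; the numerator
    is a bait-replicate channel (both replicates share the same mean).
    E.g. a true-proximal protein on the spatial-control axis has expected
    ratio ``bait_effect``; any non-contaminant class on that axis other
    than the bait and true proximal has expected ratio 0.
    """
    if cls not in CLASSES:
        raise ValidationError(f"unknown class {cls!r}")
    if axis not in AXES:
        raise ValidationError(f"unknown axis {axis!r}")
    effects = _effect_matrix(config)[cls]
    denominator = "no_ligase" if axis == "vs_no_ligase" else "spatial_control"
    return effects["bait_rep1"] - effects[denominator]


def _accessions(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """(accessions, class labels) in generation order: bait first."""
    accessions = [BAIT_ACCESSION]
    classes = ["bait"]
    blocks = (
        ("TP", "true_proximal", config.n_true_proximal),
        ("BG", "background", config.n_background),
        ("ER", "er_fp", config.n_er_fp),
        ("CM", "cm_fp", config.n_cm_fp),
        ("CT", "contaminant", config.n_contaminant),
    )
    for prefix, cls, count in blocks:
        for i in range(count):
            accessions.append(f"{prefix}{i + 1:05d}")
            classes.append(cls)
    return accessions, classes


def generate_experiment(
    config: SimulationConfig,
) -> tuple[
    list[ProteinQuantRecord],
    SyntheticTruth,
    tuple[CompartmentList, CompartmentList],
]:
    """Simulate one 4-plex experiment.

    Returns the quantification records (one per protein, bait included),
    the ground-truth class labels, and the two compartment lists containing
    exactly the simulated ER-membrane and cell-membrane false-positive
    accessions.
    """
    rng = np.random.default_rng(config.seed)
    accessions, classes = _accessions(config)
    n = len(accessions)

    base = rng.normal(config.base_log_intensity, config.base_sd, n)

    # bivariate replicate deviations via Cholesky of [[1, rho], [rho, 1]]
    rho = config.replicate_rho
    z = rng.standard_normal((n, 2))
    d1 = config.effect_sd * z[:, 0]
    d2 = config.effect_sd * (
        rho * z[:, 0] + np.sqrt(max(1.0 - rho * rho, 0.0)) * z[:, 1]
    )

    noise = rng.normal(0.0, config.noise_sd, (n, len(CHANNEL_ROLES)))
    peptides = 1 + rng.poisson(config.peptide_lambda - 1.0, n)
    # the bait is a very large protein: far more tryptic peptides than average
    peptides[0] += 16

    effects = _effect_matrix(config)
    log2_intensity = np.empty((n, len(CHANNEL_ROLES)))
    for j, role in enumerate(CHANNEL_ROLES):
        class_effect = np.array([effects[c][role] for c in classes])
        log2_intensity[:, j] = base + class_effect + noise[:, j]
    log2_intensity[:, CHANNEL_ROLES.index("bait_rep1")] += d1
    log2_intensity[:, CHANNEL_ROLES.index("bait_rep2")] += d2
    intensity = np.exp2(log2_intensity)

    labels_by_role = config.channel_roles
    records = [
        ProteinQuantRecord(
            accession=accessions[i],
            gene_symbol=accessions[i].lower(),
            unique_peptides=int(peptides[i]),
            intensities={
                labels_by_role[role]: float(intensity[i, j])
                for j, role in enumerate(CHANNEL_ROLES)
            },
        )
        for i in range(n)
    ]
    truth = SyntheticTruth(labels=dict(zip(accessions, classes)))
    er = CompartmentList(
        name="ER_membrane",
        accessions=frozenset(
            a for a, c in zip(accessions, classes) if c == "er_fp"
        ),
    )
    cm = CompartmentList(
        name="cell_membrane",
        accessions=frozenset(
            a for a, c in zip(accessions, classes) if c == "cm_fp"
        ),
    )
    return records, truth, (er, cm)


def recovery_metrics(
    final_accessions: set[str] | frozenset[str] | list[str],
    truth: SyntheticTruth,
) -> dict[str, float]:
    """Recall and precision of true-proximal recovery for a final list.

    Recall is the fraction of simulated true-proximal proteins present in
    the final list; precision the fraction of true proximals among the
    final entries, the bait excluded (recovering the bait is not a
    discovery).
    """
    final = set(final_accessions)
    true_proximal = truth.accessions_of("true_proximal")
    if not true_proximal:
        raise ValidationError("truth contains no true_proximal proteins")
    hits = final & true_proximal
    non_bait = final - truth.accessions_of("bait")
    return {
        "recall": len(hits) / len(true_proximal),
        "precision": len(hits) / len(non_bait) if non_bait else 0.0,
        "n_final": float(len(final)),
        "n_true_proximal": float(len(true_proximal)),
    }


def write_experiment(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Simulate and write quant table, FP lists, truth and config to a directory.

    Returns the paths written, keyed by artifact name.  Used by the
    ``simulate`` CLI subcommand; file contents are bit-identical for a
    fixed config.
    """
    import dataclasses
    import json
    from pathlib import Path

    from .io import write_compartment_list, write_quant_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth, (er, cm) = generate_experiment(config)
    paths = {
        "quant_table": str(out / "quant.tsv"),
        "fp_list_er": str(out / "fp_er_membrane.txt"),
        "fp_list_cm": str(out / "fp_cell_membrane.txt"),
        "truth": str(out / "truth.tsv"),
        "config": str(out / "simulation_config.json"),
    }
    write_quant_table(records, paths["quant_table"])
    write_compartment_list(er, paths["fp_list_er"])
    write_compartment_list(cm, paths["fp_list_cm"])
    with open(paths["truth"], "w") as handle:
        handle.write("accession\tclass\n")
        for accession, cls in truth.labels.items():
            handle.write(f"{accession}\t{cls}\n")
    with open(paths["config"], "w") as handle:
        json.dump(dataclasses.asdict(config), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths
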