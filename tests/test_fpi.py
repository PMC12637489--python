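"""The FPI-cutoff contract, filter application and proteome assembly."""

import math

import numpy as np
import pytest

from turboprox import (
    CompartmentList,
    EnrichmentTable,
    ValidationError,
    apply_filter,
    build_proteome,
    cutoff_at_fpi,
    fold_reduction,
    fpi_curve,
    generate_experiment,
)
from turboprox.fpi import CutoffResult
from turboprox.io import AXES, REPLICATES


def table(values, axis="vs_no_ligase", replicate="rep1"):
    return EnrichmentTable(axis=axis, replicate=replicate, values=values)


def fp_table(ratios, prefix="FP"):
    values = {f"{prefix}{i}": float(v) for i, v in enumerate(ratios)}
    comp = CompartmentList(name="ER_membrane", accessions=frozenset(values))
    return table(values), comp


def brute_force_cutoff(ratios, target):
    """Independent oracle: exhaustive search over all candidate cutoffs."""
    n = len(ratios)
    best = None
    for candidate in sorted(set(ratios)):
        fpi = sum(1 for v in ratios if v > candidate) / n
        if fpi <= target and (best is None or candidate < best):
            best = candidate
    return best


class TestFpiCurve:
    def test_degenerate_all_equal(self):
        ratios, comp = fp_table([2.5, 2.5, 2.5])
        curve = fpi_curve(ratios, comp)
        assert curve.points == ((2.5, 0.0),)
        assert curve.n_fp_observed == 3

    def test_enumerated_curve(self):
        ratios, comp = fp_table([1.0, 2.0, 3.0, 4.0])
        curve = fpi_curve(ratios, comp)
        assert curve.points == (
            (1.0, 0.75),
            (2.0, 0.5),
            (3.0, 0.25),
            (4.0, 0.0),
        )

    def test_fpi_non_increasing_on_random_input(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            values = rng.choice(
                rng.normal(0, 2, 10), size=rng.integers(5, 60)
            )  # duplicates on purpose
            ratios, comp = fp_table(values)
            curve = fpi_curve(ratios, comp)
            fpis = [p[1] for p in curve.points]
            assert all(a >= b for a, b in zip(fpis, fpis[1:]))
            assert fpis[-1] == 0.0

    def test_empty_intersection_names_the_list(self):
        ratios = table({"P1": 1.0})
        comp = CompartmentList(name="ER_membrane", accessions=frozenset({"Q1"}))
        with pytest.raises(ValidationError, match="ER_membrane"):
            fpi_curve(ratios, comp)

    def test_non_list_proteins_ignored(self):
        ratios, comp = fp_table([1.0, 2.0])
        ratios.values["OTHER"] = 99.0
        curve = fpi_curve(ratios, comp)
        assert curve.n_fp_observed == 2
        assert curve.points[-1] == (2.0, 0.0)


class TestCutoffAtFpi:
    def test_three_percent_above_construction(self):
        # 100 distinct FP ratios 0.01..1.00 at target 0.03: exactly the top
        # three ratios may exceed the cutoff, so the cutoff is 0.97
        values = [round(0.01 * i, 2) for i in range(1, 101)]
        ratios, comp = fp_table(values)
        result = cutoff_at_fpi(fpi_curve(ratios, comp), 0.03)
        assert result.cutoff == pytest.approx(0.97)
        assert result.n_fp_above == 3
        assert result.achieved_fpi == pytest.approx(0.03)

    def test_floor_to_zero_exceedances(self):
        values = [float(i) for i in range(10)]
        ratios, comp = fp_table(values)
        result = cutoff_at_fpi(fpi_curve(ratios, comp), 0.05)
        assert result.cutoff == 9.0
        assert result.n_fp_above == 0
        assert result.achieved_fpi == 0.0

    def test_ties_collapse_toward_fewer_exceedances(self):
        # ties at the selected order statistic: counting is still strict,
        # so the guarantee holds by direct count
        values = [0.0] * 50 + [1.0] * 45 + [2.0] * 5
        ratios, comp = fp_table(values)
        result = cutoff_at_fpi(fpi_curve(ratios, comp), 0.03)
        n_above = sum(1 for v in values if v > result.cutoff)
        assert n_above == result.n_fp_above
        assert n_above / len(values) <= 0.03

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_target_rejected(self, target):
        ratios, comp = fp_table([1.0, 2.0])
        with pytest.raises(ValidationError):
            cutoff_at_fpi(fpi_curve(ratios, comp), target)

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(1, 200))
            pool = rng.normal(0, 1, max(n // 3, 1))  # force ties
            values = rng.choice(pool, size=n)
            target = float(rng.uniform(0.01, 0.3))
            ratios, comp = fp_table(values)
            result = cutoff_at_fpi(fpi_curve(ratios, comp), target)
            assert result.cutoff == brute_force_cutoff(values, target)

    def test_guarantee_holds_with_heavy_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            values = rng.choice([0.0, 0.5, 1.0], size=rng.integers(3, 80))
            target = float(rng.uniform(0.01, 0.2))
            ratios, comp = fp_table(values)
            result = cutoff_at_fpi(fpi_curve(ratios, comp), target)
            assert result.achieved_fpi <= target

    def test_cutoff_monotone_and_survivors_nested(self):
        rng = np.random.default_rng(3)
        fp_values = rng.normal(0, 1, 120)
        ratios, comp = fp_table(fp_values)
        candidates = table(
            {f"C{i}": float(v) for i, v in enumerate(rng.normal(1, 1.5, 500))}
        )
        curve = fpi_curve(ratios, comp)
        strict = cutoff_at_fpi(curve, 0.03)
        loose = cutoff_at_fpi(curve, 0.05)
        assert strict.cutoff >= loose.cutoff
        assert apply_filter(candidates, strict) <= apply_filter(candidates, loose)


class TestApplyFilter:
    def test_all_below_gives_empty_set(self):
        cutoff = CutoffResult(cutoff=5.0, target_fpi=0.03, achieved_fpi=0.0, n_fp_above=0)
        assert apply_filter(table({"P1": 1.0, "P2": 4.9}), cutoff) == set()

    def test_strict_exceedance(self):
        cutoff = CutoffResult(cutoff=0.5, target_fpi=0.03, achieved_fpi=0.0, n_fp_above=0)
        assert apply_filter(table({"P1": 5.0, "P2": -1.0, "P3": 0.5}), cutoff) == {"P1"}

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(4)
        values = {f"P{i}": float(v) for i, v in enumerate(rng.normal(0, 2, 300))}
        for threshold in rng.normal(0, 2, 10):
            cutoff = CutoffResult(
                cutoff=float(threshold), target_fpi=0.03, achieved_fpi=0.0, n_fp_above=0
            )
            expected = {a for a, v in values.items() if v > threshold}
            assert apply_filter(table(values), cutoff) == expected


def four_tables(per_table_values):
    return {
        (axis, rep): table(dict(per_table_values), axis=axis, replicate=rep)
        for axis in AXES
        for rep in REPLICATES
    }


class TestBuildProteome:
    def test_replicate_intersection(self):
        values = {a: float(i) for i, a in enumerate(["A", "B", "C", "BAIT"])}
        ratios = four_tables(values)
        pass_sets = {
            ("vs_no_ligase", "rep1"): {"A", "B", "BAIT"},
            ("vs_spatial_control", "rep1"): {"A", "B", "BAIT"},
            ("vs_no_ligase", "rep2"): {"B", "C", "BAIT"},
            ("vs_spatial_control", "rep2"): {"B", "C", "BAIT"},
        }
        proteome = build_proteome(pass_sets, ratios, "BAIT")
        assert set(proteome.accessions()) == {"B", "BAIT"}
        bait_entry = next(e for e in proteome.entries if e.accession == "BAIT")
        assert "bait" in bait_entry.tags

    def test_within_replicate_filters_intersect(self):
        values = {a: 1.0 for a in "ABC"}
        ratios = four_tables(values)
        pass_sets = {
            ("vs_no_ligase", "rep1"): {"A", "B"},
            ("vs_spatial_control", "rep1"): {"B", "C"},
            ("vs_no_ligase", "rep2"): {"A", "B", "C"},
            ("vs_spatial_control", "rep2"): {"A", "B", "C"},
        }
        proteome = build_proteome(pass_sets, ratios, "BAIT")
        assert proteome.accessions() == ["B"]

    def test_empty_intersection_keeps_provenance(self):
        ratios = four_tables({"A": 1.0})
        pass_sets = {key: set() for key in ratios}
        proteome = build_proteome(
            pass_sets, ratios, "BAIT", provenance={"note": "kept"}
        )
        assert len(proteome) == 0
        assert proteome.provenance == {"note": "kept"}

    def test_ranked_by_mean_spatial_enrichment(self):
        rng = np.random.default_rng(5)
        accessions = [f"P{i}" for i in range(20)]
        ratios = {
            (axis, rep): table(
                {a: float(v) for a, v in zip(accessions, rng.normal(0, 2, 20))},
                axis=axis,
                replicate=rep,
            )
            for axis in AXES
            for rep in REPLICATES
        }
        pass_sets = {key: set(accessions) for key in ratios}
        proteome = build_proteome(pass_sets, ratios, "none")
        means = [e.mean_enrichment for e in proteome.entries]
        assert means == sorted(means, reverse=True)
        assert [e.rank for e in proteome.entries] == list(range(1, 21))
        for entry in proteome.entries:
            expected = (
                ratios[("vs_spatial_control", "rep1")].values[entry.accession]
                + ratios[("vs_spatial_control", "rep2")].values[entry.accession]
            ) / 2
            assert entry.mean_enrichment == pytest.approx(expected)

    def test_fp_list_members_flagged_not_removed(self):
        values = {"A": 1.0, "E1": 2.0}
        ratios = four_tables(values)
        pass_sets = {key: {"A", "E1"} for key in ratios}
        er = CompartmentList(name="ER_membrane", accessions=frozenset({"E1"}))
        proteome = build_proteome(pass_sets, ratios, "none", fp_lists=(er,))
        flagged = next(e for e in proteome.entries if e.accession == "E1")
        assert "fp_list:ER_membrane" in flagged.tags
        assert len(proteome) == 2

    def test_missing_bait_warns_not_errors(self, caplog):
        ratios = four_tables({"A": 1.0})
        pass_sets = {key: {"A"} for key in ratios}
        with caplog.at_level("WARNING"):
            proteome = build_proteome(pass_sets, ratios, "ABSENT")
        assert len(proteome) == 1
        assert any("ABSENT" in m for m in caplog.messages)


class TestFoldReduction:
    def test_arithmetic(self):
        assert fold_reduction(5000, 100) == 50.0
        assert fold_reduction(100, 100) == 1.0

    def test_empty_final_list_reported_infinite(self):
        assert math.isinf(fold_reduction(10, 0))

    def test_matches_division_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            before = int(rng.integers(1, 10_000))
            after = int(rng.integers(1, before + 1))
            assert fold_reduction(before, after) == before / after


class TestSyntheticRecovery:
    def test_bait_ranks_first_on_default_seed(self, tiny_sim_config):
        from turboprox import BAIT_ACCESSION
        from turboprox.pipeline import PipelineConfig, run_pipeline
        from turboprox.simulate import write_experiment

        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            paths = write_experiment(tiny_sim_config, tmp + "/sim")
            config = PipelineConfig(
                quant_table=paths["quant_table"],
                fp_list_er=paths["fp_list_er"],
                fp_list_cm=paths["fp_list_cm"],
                bait=BAIT_ACCESSION,
                out_dir=tmp + "/run",
            )
            result = run_pipeline(config)
        assert len(result.proteome) > 0
        assert result.proteome.entries[0].accession == BAIT_ACCESSION
        assert result.proteome.entries[0].rank == 1

    def test_no_effect_means_no_preferential_recovery(self):
        # with bait_effect = 0 the true-proximal class is exchangeable with
        # background: its filter pass rate must be statistically
        # indistinguishable from background's (two-proportion z, alpha=0.01)
        from statsmodels.stats.proportion import proportions_ztest

        from turboprox import SimulationConfig
        from turboprox.enrichment import log2_ratio, normalize_channels
        from turboprox.io import DEFAULT_CHANNEL_ROLES

        config = SimulationConfig(
            n_background=2000,
            n_true_proximal=500,
            n_er_fp=150,
            n_cm_fp=150,
            n_contaminant=50,
            bait_effect=0.0,
            seed=23,
        )
        records, truth, (er, cm) = generate_experiment(config)
        records = normalize_channels(records)
        roles = DEFAULT_CHANNEL_ROLES
        passed = {}
        for cls in ("true_proximal", "background"):
            members = truth.accessions_of(cls)
            survivors = set(members)
            for axis, denominator, comp, target in (
                ("vs_no_ligase", "no_ligase", er, 0.03),
                ("vs_spatial_control", "spatial_control", cm, 0.05),
            ):
                ratios = log2_ratio(
                    records,
                    roles["bait_rep1"],
                    roles[denominator],
                    axis=axis,
                    replicate="rep1",
                )
                cutoff = cutoff_at_fpi(fpi_curve(ratios, comp), target)
                survivors &= apply_filter(ratios, cutoff)
            passed[cls] = (len(survivors), len(members))
        counts = [passed["true_proximal"][0], passed["background"][0]]
        nobs = [passed["true_proximal"][1], passed["background"][1]]
        _, p_value = proportions_ztest(counts, nobs)
        assert p_value > 0.01
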