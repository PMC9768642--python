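import json

import numpy as np
import pytest

from segtrends._errors import ConfigError, DatasetError, EmptySelectionError
from segtrends.io_dataset import PERIODS
from segtrends.median_permutation import PermutationConfig
from segtrends.synthetic_data import generate_dataset, preset_config
from segtrends.trend_pipeline import (
    AnalysisPlan,
    RunConfig,
    enrolment_analyses,
    family_range_by_interval,
    jackknife_taxa,
    rarefied_range,
    run_all,
    run_timescale,
    sequential_pairs,
)
from .conftest import make_record

FAST = PermutationConfig(n_permutations=300, seed=7)


def fast_plan(**kwargs):
    kwargs.setdefault("permutation", FAST)
    return AnalysisPlan(**kwargs)


class TestRunTimescale:
    def test_two_identical_bins_p_one(self):
        records = [
            make_record(i, period=p, thorax=9, pygidium=5)
            for i in range(20)
            for p in ("Cambrian", "Ordovician")
        ]
        results = run_timescale(records, fast_plan(variables=("thorax",)))
        assert results["thorax"].p("Cambrian", "Ordovician") == 1.0

    def test_one_result_per_variable(self, toy_records):
        results = run_timescale(toy_records, fast_plan())
        assert set(results) == {"thorax", "pygidium", "trunk", "proportion"}

    def test_sequential_is_adjacent_subset(self, toy_records):
        results = run_timescale(toy_records, fast_plan(variables=("thorax",)))
        result = results["thorax"]
        seq = sequential_pairs(result)
        assert seq == tuple(zip(PERIODS, PERIODS[1:]))
        assert set(seq) <= set(result.d)

    def test_single_bin_errors(self):
        records = [make_record(i, period="Cambrian") for i in range(5)]
        with pytest.raises(EmptySelectionError):
            run_timescale(records, fast_plan(variables=("thorax",)))

    def test_taxon_scope(self, shift_carrier_records):
        results = run_timescale(
            shift_carrier_records,
            fast_plan(variables=("thorax",), taxon_scope=("Stable",)),
        )
        assert results["thorax"].p("Cambrian", "Ordovician") == 1.0

    def test_invalid_plan(self):
        with pytest.raises(ConfigError):
            AnalysisPlan(variables=())
        with pytest.raises(ConfigError):
            AnalysisPlan(timescale="aeon")


class TestJackknife:
    def test_removing_shift_carrier_flips(self, shift_carrier_records):
        report = jackknife_taxa(
            shift_carrier_records, fast_plan(variables=("thorax",))
        )
        pair = ("Cambrian", "Ordovician")
        assert report.baseline["thorax"].p_adjusted[pair] <= 0.05
        assert report.by_taxon["Shifter"]["thorax"].p_adjusted[pair] == 1.0
        flips = {(f.left_out, f.pair) for f in report.flips}
        assert ("Shifter", pair) in flips
        assert ("Stable", pair) not in flips

    def test_absent_taxon_named_in_error(self, shift_carrier_records):
        with pytest.raises(DatasetError, match="Ghostida"):
            jackknife_taxa(
                shift_carrier_records,
                fast_plan(variables=("thorax",)),
                taxa=["Ghostida"],
            )

    def test_zero_impact_taxon_recovers_baseline(self, shift_carrier_records):
        # an order contributing no pygidium counts cannot change the
        # pygidium analysis when removed
        ghosts = [
            make_record(900 + i, order_name="Ghostida", family_name="Ghostida_fam1",
                        period=p, thorax=7, pygidium=None)
            for i, p in enumerate(("Cambrian", "Ordovician"))
        ]
        report = jackknife_taxa(
            shift_carrier_records + ghosts, fast_plan(variables=("pygidium",))
        )
        assert (
            report.by_taxon["Ghostida"]["pygidium"].p_adjusted
            == report.baseline["pygidium"].p_adjusted
        )

    def test_degenerate_rerun_not_fatal(self):
        # order A occupies two bins, order B only one; leaving A out
        # leaves a single bin, which must be flagged, not fatal
        records = [
            make_record(i, period="Cambrian", order_name="A", thorax=8)
            for i in range(10)
        ]
        records += [
            make_record(100 + i, period="Ordovician", order_name="A", thorax=8)
            for i in range(10)
        ]
        records += [
            make_record(200 + i, period="Permian", order_name="B", thorax=12)
            for i in range(10)
        ]
        report = jackknife_taxa(records, fast_plan(variables=("thorax",)))
        assert "B" in report.by_taxon  # removing B still leaves 2 bins
        assert "A" in report.degenerate
        assert "A" not in report.by_taxon

    def test_family_grouping(self, shift_carrier_records):
        report = jackknife_taxa(
            shift_carrier_records, fast_plan(variables=("thorax",)), grouping="family"
        )
        assert set(report.by_taxon) == {"Shifter_fam1", "Stable_fam1"}


@pytest.fixture(scope="module")
def contraction_records():
    return generate_dataset(preset_config("range_contraction", seed=7))


class TestRarefiedRange:

    def test_full_subsample_equals_observed(self, contraction_records):
        result = rarefied_range(contraction_records, "thorax", n_iterations=50, n_sub=60)
        for label, ranges in result.ranges.items():
            assert np.all(ranges == result.observed_range[label])

    def test_rarefied_never_exceeds_observed(self, contraction_records):
        result = rarefied_range(
            contraction_records, "thorax", n_iterations=100, n_sub=10, seed=1
        )
        for label, ranges in result.ranges.items():
            assert np.all(ranges <= result.observed_range[label])

    def test_contraction_fixture_monotone(self, contraction_records):
        result = rarefied_range(contraction_records, "thorax", n_iterations=300, seed=2)
        medians = [float(np.median(result.ranges[p])) for p in PERIODS]
        assert medians == sorted(medians, reverse=True)

    def test_n_sub_too_large(self, contraction_records):
        with pytest.raises(ConfigError):
            rarefied_range(contraction_records, "thorax", n_sub=61)

    def test_mean_range_nondecreasing_in_n_sub(self, contraction_records):
        means = []
        for n_sub in (5, 15, 30):
            result = rarefied_range(
                contraction_records, "thorax", n_iterations=300, n_sub=n_sub, seed=3
            )
            means.append(np.mean([r.mean() for r in result.ranges.values()]))
        assert means == sorted(means)


class TestFamilyRanges:
    def test_monomorphic_families(self):
        records = [
            make_record(i, period="Cambrian", family_name=f"fam{i % 3}", thorax=10)
            for i in range(12)
        ]
        result = family_range_by_interval(records)
        assert result.median_range() == {"Cambrian": 0.0}

    def test_range_arithmetic(self):
        records = [
            make_record(i, period="Silurian", family_name="famX", thorax=t)
            for i, t in enumerate((6, 8, 11))
        ]
        result = family_range_by_interval(records)
        assert result.per_bin["Silurian"] == [("famX", 3, 5.0)]

    def test_singletons_excluded(self):
        records = [
            make_record(0, period="Cambrian", family_name="famA", thorax=5),
            make_record(1, period="Cambrian", family_name="famA", thorax=9),
            make_record(2, period="Cambrian", family_name="famB", thorax=30),
        ]
        result = family_range_by_interval(records)
        assert [f for f, _, _ in result.per_bin["Cambrian"]] == ["famA"]

    def test_all_singletons_errors(self):
        records = [make_record(i, family_name=f"fam{i}") for i in range(4)]
        with pytest.raises(EmptySelectionError):
            family_range_by_interval(records)

    def test_min_species_guard(self, toy_records):
        with pytest.raises(ConfigError):
            family_range_by_interval(toy_records, min_species=1)

    def test_conservation_fixture_strictly_decreasing(self):
        records = generate_dataset(preset_config("family_conservation", seed=7))
        medians = list(family_range_by_interval(records).median_range().values())
        assert len(medians) == 6
        assert all(a > b for a, b in zip(medians, medians[1:]))


@pytest.fixture(scope="module")
def labelled_records():
    records = []
    i = 0
    for period in ("Cambrian", "Ordovician"):
        for strategy, thorax in (
            ("spheroidal", 10),
            ("cylindrical", 10),
            ("discoidal", 4),
        ):
            for j in range(15):
                records.append(
                    make_record(i, period=period, thorax=thorax + j % 3 - 1,
                                pygidium=6, enrolment=strategy)
                )
                i += 1
    return records


class TestEnrolment:
    def test_no_labels_errors(self, toy_records):
        with pytest.raises(EmptySelectionError):
            enrolment_analyses(toy_records, FAST)

    def test_low_median_strategy_detected(self, labelled_records):
        report = enrolment_analyses(labelled_records, FAST)
        between = report.between["thorax"]
        assert between.p("discoidal", "spheroidal") <= 0.05
        assert between.p("discoidal", "cylindrical") <= 0.05
        assert between.p("cylindrical", "spheroidal") > 0.05

    def test_within_strategy_flat(self, labelled_records):
        report = enrolment_analyses(labelled_records, FAST)
        for strategy, results in report.within.items():
            assert results["thorax"].p("Cambrian", "Ordovician") == 1.0

    def test_small_groups_dropped(self, labelled_records):
        rare = [
            make_record(999 + i, period="Cambrian", thorax=2, pygidium=2,
                        enrolment="basket")
            for i in range(3)
        ]
        report = enrolment_analyses(labelled_records + rare, FAST)
        assert "basket" not in report.between["thorax"].group_labels
        assert any("basket" in msg for msg in report.skipped)


@pytest.fixture(scope="module")
def null_records():
    return generate_dataset(preset_config("global_null", seed=3))


class TestRunAll:

    def test_same_seed_byte_identical_trees(self, null_records, tmp_path):
        config = RunConfig(n_permutations=100, rarefaction_iterations=50, seed=5)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        run_all(null_records, config, dir_a)
        run_all(null_records, config, dir_b)
        names_a = sorted(p.name for p in dir_a.iterdir())
        assert names_a == sorted(p.name for p in dir_b.iterdir())
        for name in names_a:
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()

    def test_manifest_contents(self, null_records, tmp_path):
        config = RunConfig(n_permutations=100, rarefaction_iterations=50, seed=5)
        run_all(null_records, config, tmp_path / "out")
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["n_records"] == len(null_records)
        assert manifest["config"]["seed"] == 5
        assert all(status == "ok" for status in manifest["stages"].values())
        for name in manifest["outputs"]:
            assert (tmp_path / "out" / name).exists()

    def test_missing_series_fails_only_that_stage(self, null_records, tmp_path):
        config = RunConfig(
            n_permutations=100,
            rarefaction_iterations=50,
            timescales=("period", "series"),
        )
        manifest = run_all(null_records, config, tmp_path / "out")
        assert manifest["stages"]["timescale_series"].startswith("error")
        assert manifest["stages"]["timescale_period"] == "ok"
        assert manifest["stages"]["rarefaction"] == "ok"
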