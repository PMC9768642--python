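"""Orchestration of the clade-wide analyses: per-variable median tests
across a timescale, leave-one-taxon-out (jackknife) sensitivity,
rarefaction of ranges, within-family range trends, and enrolment-strategy
subsets.

Sequential (adjacent-bin) comparisons are extracted from the single
all-pairs analysis, never re-tested, so the familywise error control is
within each all-pairs analysis.  Analyses across different variables and
timescales are deliberately not jointly corrected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ConfigError, DatasetError, EmptySelectionError
from .io_dataset import (
    PERIODS,
    VARIABLES,
    GroupedSample,
    SegmentRecord,
    group_by,
    write_dataset,
)
from .median_permutation import (
    PairwiseMedianResult,
    PermutationConfig,
    run_median_test,
)

log = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class AnalysisPlan:
    """What to test: variables, timescale, optional taxon filter, and the
    permutation settings."""

    variables: tuple[str, ...] = VARIABLES
    timescale: str = "period"
    taxon_scope: tuple[str, ...] | None = None  # None = all orders
    permutation: PermutationConfig = field(default_factory=PermutationConfig)

    def __post_init__(self) -> None:
        if not self.variables:
            raise ConfigError("plan needs at least one variable")
        unknown = set(self.variables) - set(VARIABLES)
        if unknown:
            raise ConfigError(f"unknown variable(s) {sorted(unknown)}")
        if self.timescale not in ("period", "series"):
            raise ConfigError("timescale must be 'period' or 'series'")


def _scope_filters(taxon_scope: tuple[str, ...] | None):
    if taxon_scope is None:
        return []
    scope = set(taxon_scope)
    return [lambda rec: rec.order_name in scope]


def run_timescale(
    records: Sequence[SegmentRecord], plan: AnalysisPlan
) -> dict[str, PairwiseMedianResult]:
    """One all-pairs median test per variable across the plan's time bins."""
    results: dict[str, PairwiseMedianResult] = {}
    for variable in plan.variables:
        sample = group_by(
            records, variable, plan.timescale, filters=_scope_filters(plan.taxon_scope)
        )
        if len(sample.labels) < 2:
            raise EmptySelectionError(
                f"variable {variable!r}: fewer than 2 non-empty {plan.timescale} bins"
            )
        results[variable] = run_median_test(sample, plan.permutation)
    return results


def sequential_pairs(result: PairwiseMedianResult) -> tuple[Pair, ...]:
    """The adjacent-bin subset of an all-pairs result (no re-testing)."""
    labels = result.group_labels
    return tuple(
        pair for pair in zip(labels, labels[1:]) if pair in result.d
    )


# ---------------------------------------------------------------------------
# jackknife


@dataclass
class JackknifeFlip:
    left_out: str
    variable: str
    pair: Pair
    baseline_rejected: bool
    jackknife_rejected: bool


@dataclass
class JackknifeReport:
    """Full reruns with one taxon removed at a time, plus the comparisons
    whose significance classification flipped relative to the all-taxa run."""

    grouping: str
    baseline: dict[str, PairwiseMedianResult]
    by_taxon: dict[str, dict[str, PairwiseMedianResult]]
    flips: list[JackknifeFlip]
    degenerate: dict[str, str]  # left-out taxon -> reason the rerun failed


def _taxon_key(record: SegmentRecord, grouping: str) -> str:
    return record.order_name if grouping == "order" else record.family_name


def jackknife_taxa(
    records: Sequence[SegmentRecord],
    plan: AnalysisPlan,
    grouping: str = "order",
    taxa: Sequence[str] | None = None,
) -> JackknifeReport:
    """Repeat :func:`run_timescale` removing one taxon at a time.

    ``grouping`` selects the taxonomic level ('order' default, 'family'
    optional).  ``taxa`` restricts which taxa are left out; naming a taxon
    absent from the data is an error.
    """
    if grouping not in ("order", "family"):
        raise ConfigError("jackknife grouping must be 'order' or 'family'")
    present = sorted({_taxon_key(rec, grouping) for rec in records if _taxon_key(rec, grouping)})
    if len(present) < 2:
        raise EmptySelectionError(f"need at least two {grouping} taxa to jackknife")
    if taxa is None:
        taxa = present
    else:
        missing = sorted(set(taxa) - set(present))
        if missing:
            raise DatasetError(f"taxa not present in the data: {missing}")

    baseline = run_timescale(records, plan)
    by_taxon: dict[str, dict[str, PairwiseMedianResult]] = {}
    degenerate: dict[str, str] = {}
    flips: list[JackknifeFlip] = []
    for taxon in taxa:
        subset = [rec for rec in records if _taxon_key(rec, grouping) != taxon]
        try:
            rerun = run_timescale(subset, plan)
        except (EmptySelectionError, DatasetError) as exc:
            degenerate[taxon] = str(exc)
            log.warning("jackknife run without %s is degenerate: %s", taxon, exc)
            continue
        by_taxon[taxon] = rerun
        for variable, base_result in baseline.items():
            jack = rerun.get(variable)
            if jack is None:
                continue
            for pair, was_rejected in base_result.rejected.items():
                if pair not in jack.p_adjusted:
                    continue
                now_rejected = jack.p_adjusted[pair] <= jack.alpha
                if now_rejected != was_rejected:
                    flips.append(
                        JackknifeFlip(taxon, variable, pair, was_rejected, now_rejected)
                    )
    return JackknifeReport(
        grouping=grouping,
        baseline=baseline,
        by_taxon=by_taxon,
        flips=flips,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefactionResult:
    """Distribution of subsampled (max - min) ranges per time bin."""

    variable: str
    n_sub: int
    n_iterations: int
    seed: int
    observed_range: dict[str, float]
    ranges: dict[str, np.ndarray]  # bin -> (n_iterations,) subsampled ranges

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, values in self.ranges.items():
            q05, med, q95 = np.percentile(values, [5, 50, 95])
            rows.append(
                {
                    "bin": label,
                    "observed_range": self.observed_range[label],
                    "median_rarefied_range": med,
                    "q05": q05,
                    "q95": q95,
                    "mean_rarefied_range": float(values.mean()),
                    "n_sub": self.n_sub,
                    "n_iterations": self.n_iterations,
                }
            )
        return pd.DataFrame(rows)


def rarefied_range(
    records: Sequence[SegmentRecord],
    variable: str,
    n_iterations: int = 1000,
    n_sub: int | None = None,
    seed: int = 0,
    grouping: str = "period",
) -> RarefactionResult:
    """Subsample every bin, without replacement, to a common size and
    record the distribution of the realized range.

    ``n_sub`` defaults to the smallest bin size; requesting more than the
    smallest bin holds is a configuration error.
    """
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")
    sample = group_by(records, variable, grouping)
    min_n = min(sample.sizes)
    if n_sub is None:
        n_sub = min_n
    if n_sub < 1 or n_sub > min_n:
        raise ConfigError(
            f"n_sub={n_sub} must be in [1, {min_n}] (the smallest bin size)"
        )
    rng = np.random.default_rng(seed)
    observed = {label: float(vals.max() - vals.min()) for label, vals in sample.groups.items()}
    ranges: dict[str, np.ndarray] = {}
    for label, values in sample.groups.items():
        sub = rng.permuted(np.tile(values, (n_iterations, 1)), axis=1)[:, :n_sub]
        ranges[label] = sub.max(axis=1) - sub.min(axis=1)
    return RarefactionResult(
        variable=variable,
        n_sub=n_sub,
        n_iterations=n_iterations,
        seed=seed,
        observed_range=observed,
        ranges=ranges,
    )


# ---------------------------------------------------------------------------
# within-family ranges


@dataclass
class FamilyRangeResult:
    """Within-family (max - min) ranges per time bin, for families with at
    least ``min_species`` sampled species in that bin."""

    variable: str
    min_species: int
    per_bin: dict[str, list[tuple[str, int, float]]]  # bin -> (family, n, range)

    def median_range(self) -> dict[str, float]:
        return {
            label: float(np.median([r for _, _, r in rows]))
            for label, rows in self.per_bin.items()
        }

    def mean_range(self) -> dict[str, float]:
        return {
            label: float(np.mean([r for _, _, r in rows]))
            for label, rows in self.per_bin.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin": label, "family": fam, "n": n, "range": rng}
            for label, fam_rows in self.per_bin.items()
            for fam, n, rng in fam_rows
        ]
        return pd.DataFrame(rows)


def family_range_by_interval(
    records: Sequence[SegmentRecord],
    variable: str = "thorax",
    min_species: int = 2,
    grouping: str = "period",
) -> FamilyRangeResult:
    """Within-family trait ranges per time bin.

    Records are pooled per (family, bin); families with fewer than
    ``min_species`` usable records in a bin carry no range information and
    are excluded.
    """
    if min_species < 2:
        raise ConfigError("min_species must be >= 2 (a singleton has no range)")
    from .io_dataset import variable_value  # local import avoids cycle at module load

    buckets: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        key = rec.period if grouping == "period" else rec.series
        value = variable_value(rec, variable)
        if key is None or value is None or not rec.family_name:
            continue
        buckets.setdefault((key, rec.family_name), []).append(value)

    per_bin: dict[str, list[tuple[str, int, float]]] = {}
    order = [p for p in PERIODS if any(k[0] == p for k in buckets)] if grouping == "period" else sorted(
        {k[0] for k in buckets}
    )
    for bin_label in order:
        rows = []
        for (key, family), values in sorted(buckets.items()):
            if key != bin_label or len(values) < min_species:
                continue
            rows.append((family, len(values), float(max(values) - min(values))))
        if rows:
            per_bin[bin_label] = rows
    if not per_bin:
        raise EmptySelectionError(
            f"no family with >= {min_species} species in any bin for {variable!r}"
        )
    return FamilyRangeResult(variable=variable, min_species=min_species, per_bin=per_bin)


# ---------------------------------------------------------------------------
# enrolment


@dataclass
class EnrolmentReport:
    """Between-strategy (pooled across the Palaeozoic) and within-strategy
    (across periods) median tests."""

    between: dict[str, PairwiseMedianResult]  # variable -> result
    within: dict[str, dict[str, PairwiseMedianResult]]  # strategy -> variable -> result
    skipped: list[str]
    min_group_n: int


def _prune_small_groups(sample: GroupedSample, min_n: int, context: str, skipped: list[str]) -> GroupedSample | None:
    kept = {label: vals for label, vals in sample.groups.items() if vals.size >= min_n}
    for label, vals in sample.groups.items():
        if vals.size < min_n:
            msg = f"{context}: group {label!r} dropped (n={vals.size} < {min_n})"
            skipped.append(msg)
            log.warning(msg)
    if len(kept) < 2:
        skipped.append(f"{context}: fewer than 2 usable groups")
        return None
    return GroupedSample(variable=sample.variable, groups=kept, n_dropped=sample.n_dropped)


def enrolment_analyses(
    records: Sequence[SegmentRecord],
    config: PermutationConfig | None = None,
    variables: tuple[str, ...] = ("thorax", "proportion"),
    min_group_n: int = 5,
) -> EnrolmentReport:
    """Median tests on the enrolment-labelled subset of the data.

    (a) between strategies, pooling all periods; (b) within each strategy,
    across periods.  Groups below ``min_group_n`` are dropped with a logged
    warning; an arm with fewer than two usable groups is recorded as
    skipped rather than failing the other arm.
    """
    config = config or PermutationConfig()
    labelled = [rec for rec in records if rec.enrolment]
    if not labelled:
        raise EmptySelectionError("no records carry an enrolment label")
    skipped: list[str] = []

    between: dict[str, PairwiseMedianResult] = {}
    for variable in variables:
        try:
            sample = group_by(labelled, variable, "enrolment")
        except EmptySelectionError as exc:
            skipped.append(f"between/{variable}: {exc}")
            continue
        pruned = _prune_small_groups(sample, min_group_n, f"between/{variable}", skipped)
        if pruned is not None:
            between[variable] = run_median_test(pruned, config)

    strategies = sorted({rec.enrolment for rec in labelled})
    within: dict[str, dict[str, PairwiseMedianResult]] = {}
    for strategy in strategies:
        subset = [rec for rec in labelled if rec.enrolment == strategy]
        per_variable: dict[str, PairwiseMedianResult] = {}
        for variable in variables:
            try:
                sample = group_by(subset, variable, "period")
            except EmptySelectionError as exc:
                skipped.append(f"within/{strategy}/{variable}: {exc}")
                continue
            pruned = _prune_small_groups(
                sample, min_group_n, f"within/{strategy}/{variable}", skipped
            )
            if pruned is not None:
                per_variable[variable] = run_median_test(pruned, config)
        if per_variable:
            within[strategy] = per_variable

    if not between and not within:
        raise EmptySelectionError(
            "enrolment analyses impossible: no arm has two usable groups; "
            + "; ".join(skipped)
        )
    return EnrolmentReport(
        between=between, within=within, skipped=skipped, min_group_n=min_group_n
    )


@dataclass
class SensitivityReport:
    """Bundle of the sensitivity analyses."""

    jackknife: JackknifeReport | None = None
    rarefaction: RarefactionResult | None = None
    family_ranges: FamilyRangeResult | None = None


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class RunConfig:
    """Master configuration for :func:`run_all`."""

    variables: tuple[str, ...] = VARIABLES
    timescales: tuple[str, ...] = ("period",)
    n_permutations: int = 10_000
    alpha: float = 0.05
    method: str = "single_step"
    seed: int = 0
    jackknife: bool = True
    jackknife_grouping: str = "order"
    rarefaction: bool = True
    rarefaction_variable: str = "thorax"
    rarefaction_iterations: int = 1000
    rarefaction_n_sub: int | None = None
    family_ranges: bool = True
    family_min_species: int = 2
    enrolment: bool = True
    enrolment_min_n: int = 5

    def permutation(self) -> PermutationConfig:
        return PermutationConfig(
            n_permutations=self.n_permutations,
            seed=self.seed,
            alpha=self.alpha,
            method=self.method,
        )


def _results_frame(results: dict[str, PairwiseMedianResult], sequential: bool) -> pd.DataFrame:
    rows = []
    for result in results.values():
        seq = set(sequential_pairs(result))
        for row in result.to_rows():
            row["sequential"] = (row["group_a"], row["group_b"]) in seq
            rows.append(row)
    frame = pd.DataFrame(rows)
    if sequential:
        frame = frame[frame["sequential"]]
    return frame


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    records: Sequence[SegmentRecord], config: RunConfig, out_dir
) -> dict:
    """Execute every enabled stage, writing CSV tables and a JSON manifest.

    Per-stage failures are captured in the manifest; re-running with the
    same records, config and seed reproduces every output byte-for-byte
    (the manifest carries no wall-clock information).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    perm = config.permutation()
    stages: dict[str, str] = {}
    outputs: list[str] = []

    clean_path = out_dir / "dataset_clean.csv"
    write_dataset(records, clean_path)
    outputs.append(clean_path.name)

    for timescale in config.timescales:
        stage = f"timescale_{timescale}"
        try:
            plan = AnalysisPlan(
                variables=config.variables, timescale=timescale, permutation=perm
            )
            results = run_timescale(records, plan)
            path = out_dir / f"{stage}.csv"
            _write_csv(_results_frame(results, sequential=False), path)
            outputs.append(path.name)
            stages[stage] = "ok"
        except (DatasetError, ConfigError) as exc:
            stages[stage] = f"error: {exc}"
            log.error("stage %s failed: %s", stage, exc)

    if config.jackknife:
        try:
            plan = AnalysisPlan(
                variables=config.variables, timescale="period", permutation=perm
            )
            report = jackknife_taxa(records, plan, grouping=config.jackknife_grouping)
            rows = []
            for taxon, results in report.by_taxon.items():
                for result in results.values():
                    for row in result.to_rows():
                        row["left_out"] = taxon
                        rows.append(row)
            path = out_dir / "jackknife.csv"
            _write_csv(pd.DataFrame(rows), path)
            outputs.append(path.name)
            flips_path = out_dir / "jackknife_flips.csv"
            _write_csv(
                pd.DataFrame([asdict(f) for f in report.flips]),
                flips_path,
            )
            outputs.append(flips_path.name)
            stages["jackknife"] = "ok"
        except (DatasetError, ConfigError) as exc:
            stages["jackknife"] = f"error: {exc}"
            log.error("stage jackknife failed: %s", exc)

    if config.rarefaction:
        try:
            result = rarefied_range(
                records,
                config.rarefaction_variable,
                n_iterations=config.rarefaction_iterations,
                n_sub=config.rarefaction_n_sub,
                seed=config.seed,
            )
            path = out_dir / "rarefaction.csv"
            _write_csv(result.summary(), path)
            outputs.append(path.name)
            stages["rarefaction"] = "ok"
        except (DatasetError, ConfigError) as exc:
            stages["rarefaction"] = f"error: {exc}"
            log.error("stage rarefaction failed: %s", exc)

    if config.family_ranges:
        try:
            result = family_range_by_interval(
                records, min_species=config.family_min_species
            )
            path = out_dir / "family_ranges.csv"
            _write_csv(result.to_frame(), path)
            outputs.append(path.name)
            stages["family_ranges"] = "ok"
        except (DatasetError, ConfigError) as exc:
            stages["family_ranges"] = f"error: {exc}"
            log.error("stage family_ranges failed: %s", exc)

    if config.enrolment:
        try:
            report = enrolment_analyses(
                records, perm, min_group_n=config.enrolment_min_n
            )
            path = out_dir / "enrolment_between.csv"
            _write_csv(_results_frame(report.between, sequential=False), path)
            outputs.append(path.name)
            rows = []
            for strategy, results in report.within.items():
                for result in results.values():
                    for row in result.to_rows():
                        row["strategy"] = strategy
                        rows.append(row)
            path = out_dir / "enrolment_within.csv"
            _write_csv(pd.DataFrame(rows), path)
            outputs.append(path.name)
            stages["enrolment"] = "ok"
        except (DatasetError, ConfigError) as exc:
            stages["enrolment"] = f"error: {exc}"
            log.error("stage enrolment failed: %s", exc)

    manifest = {
        "tool": "segtrends",
        "version": __version__,
        "n_records": len(records),
        "input_digest": _sha256(clean_path),
        "config": asdict(config),
        "stages": stages,
        "outputs": sorted(outputs),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["output_digests"] = {name: _sha256(out_dir / name) for name in sorted(outputs)}
    return manifest
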