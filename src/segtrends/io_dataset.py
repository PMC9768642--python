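"""Data model and I/O for species-level segment-count tables.

A dataset is a CSV (RFC-4180, UTF-8, header row) with one row per species
carrying integer segment counts for the thorax and pygidium together with
taxonomic (order, family) and stratigraphic (period, optionally series)
metadata and an optional enrolment-strategy label.  Arbitrary source
headers are supported through a user-supplied column mapping; internally
everything is canonicalized.

Derived analysis variables:

* ``trunk`` — thorax + pygidium (exact integer arithmetic),
* ``proportion`` — pygidium / trunk, the fraction of trunk segments fused
  into the pygidium, in ``(0, 1]``.

Records with a missing pygidium count are retained for thorax-only
analyses and silently excluded from pygidium / trunk / proportion
groupings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from ._errors import (
    EmptySelectionError,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: The six Palaeozoic periods, oldest first.  This is a closed set.
PERIODS: tuple[str, ...] = (
    "Cambrian",
    "Ordovician",
    "Silurian",
    "Devonian",
    "Carboniferous",
    "Permian",
)

#: Chronological ordering for the finer timescale (global series and, for
#: the Carboniferous, subsystems).  Labels not in this registry sort after
#: the known ones, alphabetically, so unknown schemes still give a
#: deterministic group order.
SERIES_ORDER: tuple[str, ...] = (
    "Terreneuvian",
    "Cambrian Series 2",
    "Miaolingian",
    "Furongian",
    "Lower Ordovician",
    "Middle Ordovician",
    "Upper Ordovician",
    "Llandovery",
    "Wenlock",
    "Ludlow",
    "Pridoli",
    "Lower Devonian",
    "Middle Devonian",
    "Upper Devonian",
    "Mississippian",
    "Pennsylvanian",
    "Cisuralian",
    "Guadalupian",
    "Lopingian",
)

#: Analysis variables.
VARIABLES: tuple[str, ...] = ("thorax", "pygidium", "trunk", "proportion")

#: Canonical column names in file order.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "species",
    "order",
    "family",
    "period",
    "series",
    "thorax",
    "pygidium",
    "enrolment",
)

#: Columns that must be present (possibly via the mapping).
REQUIRED_COLUMNS: tuple[str, ...] = ("species", "order", "family", "period", "thorax")

GROUPINGS: tuple[str, ...] = ("period", "series", "order", "family", "enrolment")

_PERIOD_LOOKUP = {p.lower(): p for p in PERIODS}
_SERIES_RANK = {s: i for i, s in enumerate(SERIES_ORDER)}


@dataclass(frozen=True)
class SegmentRecord:
    """One species: segment counts plus taxonomic/stratigraphic metadata.

    Invariants (enforced at construction):

    * ``thorax >= 0`` and, when present, ``pygidium >= 0``, both integers;
    * the trunk exists: ``thorax + pygidium >= 1`` (with a missing
      pygidium, ``thorax >= 1``);
    * ``period`` is one of the six Palaeozoic periods.
    """

    species_id: str
    order_name: str
    family_name: str
    period: str
    thorax: int
    pygidium: int | None = None
    series: str | None = None
    enrolment: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.thorax, (int, np.integer)) or isinstance(self.thorax, bool):
            raise ValidationError(f"thorax must be an integer, got {self.thorax!r}")
        if self.thorax < 0:
            raise ValidationError(f"thorax must be >= 0, got {self.thorax}")
        if self.pygidium is not None:
            if not isinstance(self.pygidium, (int, np.integer)) or isinstance(self.pygidium, bool):
                raise ValidationError(f"pygidium must be an integer, got {self.pygidium!r}")
            if self.pygidium < 0:
                raise ValidationError(f"pygidium must be >= 0, got {self.pygidium}")
            if self.thorax + self.pygidium < 1:
                raise ValidationError("trunk must have at least one segment")
        elif self.thorax < 1:
            raise ValidationError(
                "a record with no pygidium count needs thorax >= 1 for the trunk to exist"
            )
        if self.period not in PERIODS:
            raise ValidationError(
                f"period {self.period!r} not in {PERIODS}; labels are canonicalized on load"
            )


@dataclass(frozen=True)
class DerivedVariables:
    """Trunk count and pygidial proportion for one record."""

    trunk: int
    proportion: float


def derive_variables(record: SegmentRecord) -> DerivedVariables:
    """Compute ``trunk = T + P`` and ``proportion = P / (T + P)``.

    Requires a pygidium count; the trunk-exists invariant guarantees the
    denominator is positive.
    """
    if record.pygidium is None:
        raise ValidationError(
            f"record {record.species_id!r} has no pygidium count; "
            "trunk/proportion are undefined"
        )
    trunk = record.thorax + record.pygidium
    if trunk == 0:  # unreachable for validated records; kept as a guard
        raise ValidationError(f"record {record.species_id!r} has an empty trunk")
    return DerivedVariables(trunk=trunk, proportion=record.pygidium / trunk)


@dataclass
class GroupedSample:
    """Named, ordered groups of numeric values ready for testing.

    ``groups`` is an insertion-ordered mapping label -> 1-D float array;
    the insertion order is the deterministic group order (chronological
    for time bins, alphabetical for taxa and enrolment types).  Every
    group is non-empty.
    """

    variable: str
    groups: dict[str, np.ndarray]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise EmptySelectionError("a grouped sample needs at least one group")
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise EmptySelectionError(f"group {label!r} is empty")
            self.groups[label] = arr

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.groups.values())


# ---------------------------------------------------------------------------
# reading / writing


def _parse_int(raw: str, column: str, row: int, issues: list[str]) -> int | None:
    text = raw.strip()
    try:
        return int(text)
    except ValueError:
        issues.append(f"row {row}: column {column!r} is not an integer: {raw!r}")
        return None


def _canonical_period(raw: str, row: int, issues: list[str]) -> str | None:
    period = _PERIOD_LOOKUP.get(raw.strip().lower())
    if period is None:
        issues.append(f"row {row}: unknown period {raw!r}")
    return period


def read_dataset(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    on_invalid: str = "raise",
) -> list[SegmentRecord]:
    """Read and validate a species-level segment-count table.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional mapping of canonical column name -> source header, for
        files whose headers differ from :data:`CANONICAL_COLUMNS`.
    on_invalid:
        ``"raise"`` (default) raises :class:`ValidationError` listing every
        offending row; ``"drop"`` rejects those rows, logging row-indexed
        diagnostics and the accepted/rejected counts.
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in CANONICAL_COLUMNS}

    try:
        handle = open(path, newline="", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read dataset {path}: {exc}") from exc

    with handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [colmap[c] for c in REQUIRED_COLUMNS if colmap[c] not in header]
        if missing:
            raise SchemaError(
                f"missing required column(s) {missing} in {path} (after mapping)"
            )
        present = {c: colmap[c] for c in CANONICAL_COLUMNS if colmap[c] in header}

        records: list[SegmentRecord] = []
        issues: list[str] = []
        for row_idx, row in enumerate(reader, start=1):
            row_issues: list[str] = []

            def get(canon: str) -> str:
                source = present.get(canon)
                return (row.get(source) or "").strip() if source else ""

            thorax = _parse_int(get("thorax"), "thorax", row_idx, row_issues)
            pyg_raw = get("pygidium")
            pygidium = (
                _parse_int(pyg_raw, "pygidium", row_idx, row_issues) if pyg_raw else None
            )
            period = _canonical_period(get("period"), row_idx, row_issues)
            if not row_issues:
                try:
                    records.append(
                        SegmentRecord(
                            species_id=get("species"),
                            order_name=get("order"),
                            family_name=get("family"),
                            period=period,
                            thorax=thorax,
                            pygidium=pygidium,
                            series=get("series") or None,
                            enrolment=get("enrolment") or None,
                        )
                    )
                except ValidationError as exc:
                    row_issues.append(f"row {row_idx}: {exc}")
            issues.extend(row_issues)

    if issues:
        if on_invalid == "raise":
            raise ValidationError(
                f"{len(issues)} invalid row(s) in {path}:\n" + "\n".join(issues)
            )
        for msg in issues:
            log.warning("rejected %s", msg)
    log.info(
        "read %s: %d record(s) accepted, %d row issue(s)", path, len(records), len(issues)
    )
    return records


def write_dataset(records: Iterable[SegmentRecord], path) -> None:
    """Write records in the canonical CSV dialect (round-trip stable)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.species_id,
                    rec.order_name,
                    rec.family_name,
                    rec.period,
                    rec.series or "",
                    rec.thorax,
                    "" if rec.pygidium is None else rec.pygidium,
                    rec.enrolment or "",
                ]
            )


# ---------------------------------------------------------------------------
# grouping


def variable_value(record: SegmentRecord, variable: str) -> float | None:
    """The value of an analysis variable for one record, or None if the
    record lacks the counts the variable needs."""
    if variable == "thorax":
        return float(record.thorax)
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    if record.pygidium is None:
        return None
    if variable == "pygidium":
        return float(record.pygidium)
    derived = derive_variables(record)
    return float(derived.trunk) if variable == "trunk" else derived.proportion


def _grouping_key(record: SegmentRecord, grouping: str) -> str | None:
    if grouping == "period":
        return record.period
    if grouping == "series":
        return record.series
    if grouping == "order":
        return record.order_name or None
    if grouping == "family":
        return record.family_name or None
    if grouping == "enrolment":
        return record.enrolment
    raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def _ordered_labels(labels: Iterable[str], grouping: str) -> list[str]:
    labels = set(labels)
    if grouping == "period":
        return [p for p in PERIODS if p in labels]
    if grouping == "series":
        known = [s for s in SERIES_ORDER if s in labels]
        unknown = sorted(labels - set(SERIES_ORDER))
        return known + unknown
    return sorted(labels)


def group_by(
    records: Sequence[SegmentRecord],
    variable: str,
    grouping: str,
    filters: Iterable[Callable[[SegmentRecord], bool]] | None = None,
) -> GroupedSample:
    """Group one analysis variable by a metadata column.

    Records lacking the grouping value or the counts the variable needs
    are dropped and counted in ``GroupedSample.n_dropped``.  Group order
    is chronological for time bins and alphabetical otherwise.
    """
    filters = list(filters or [])
    buckets: dict[str, list[float]] = {}
    dropped = 0
    for rec in records:
        if not all(pred(rec) for pred in filters):
            continue
        key = _grouping_key(rec, grouping)
        value = variable_value(rec, variable)
        if key is None or value is None:
            dropped += 1
            continue
        buckets.setdefault(key, []).append(value)
    if not buckets:
        raise EmptySelectionError(
            f"no records usable for variable={variable!r} grouped by {grouping!r}"
        )
    ordered = {
        label: np.asarray(buckets[label], dtype=float)
        for label in _ordered_labels(buckets, grouping)
    }
    for label, values in ordered.items():
        log.debug("group %s: n=%d", label, values.size)
    return GroupedSample(variable=variable, groups=ordered, n_dropped=dropped)
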