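"""Synthetic species-level datasets with the statistical structure the
analyses assume: skewed, heavy-tailed count distributions with unequal
per-bin sample sizes, hierarchical family structure within orders, and
categorical enrolment labels.

The workhorse count law is a negative binomial shifted by a minimum count
with optional right-tail contamination (a small probability of much larger
values) to produce heavy tails.  A ``symmetric_range`` law builds values
symmetric around a center with forced endpoints, so the realized median
equals the center exactly and the realized range equals twice the
half-width exactly — the construction behind the range-contraction and
family-conservation presets.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; identical seed and config give a bit-identical
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._errors import ConfigError
from .io_dataset import PERIODS, SegmentRecord, write_dataset

ORDERS: tuple[str, ...] = ("Phacopida", "Proetida", "Asaphida", "Ptychopariida")
ENROLMENT_TYPES: tuple[str, ...] = ("spheroidal", "discoidal", "cylindrical", "other")

BASES = ("negbinom", "symmetric_range", "constant")
FAMILY_MODES = ("none", "clustered", "range_locked")

#: Unequal per-bin sample sizes used by the presets (oldest bin largest,
#: youngest smallest, echoing the real dataset's imbalance).
DEFAULT_N_PER_BIN: dict[str, int] = {
    "Cambrian": 150,
    "Ordovician": 120,
    "Silurian": 40,
    "Devonian": 60,
    "Carboniferous": 40,
    "Permian": 25,
}

PRESETS = ("global_null", "pygidium_trend", "range_contraction", "family_conservation")


@dataclass(frozen=True)
class CountLaw:
    """Per-bin distribution of an integer segment count.

    negbinom: ``min_count + NB(dispersion, mean)`` (+ optional additive
    Poisson contamination of the right tail); symmetric_range: values
    symmetric around ``center`` with forced endpoints ``center ±
    half_width``; constant: every value equals ``value``.  ``shift`` is an
    integer location shift added last.
    """

    base: str = "negbinom"
    min_count: int = 2
    mean: float = 8.0
    dispersion: float = 1.5
    contamination: float = 0.0
    contamination_scale: float = 3.0
    center: int = 10
    half_width: int = 5
    value: int = 8
    shift: int = 0

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ConfigError(f"unknown count-law base {self.base!r}; expected {BASES}")
        if self.base == "negbinom":
            if self.mean < 0 or self.dispersion <= 0:
                raise ConfigError("negbinom needs mean >= 0 and dispersion > 0")
            if not 0.0 <= self.contamination < 1.0:
                raise ConfigError("contamination must be a probability in [0, 1)")
        if self.base == "symmetric_range" and self.half_width < 0:
            raise ConfigError("half_width must be >= 0")
        if self.min_count < 0:
            raise ConfigError("min_count must be >= 0")

    # analytic shape of the uncontaminated negbinom component, for tests
    def negbinom_skewness(self) -> float:
        r = self.dispersion
        p = r / (r + self.mean)
        return (2 - p) / np.sqrt(r * (1 - p))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.base == "constant":
            values = np.full(n, self.value, dtype=np.int64)
        elif self.base == "negbinom":
            if self.mean == 0:
                values = np.full(n, self.min_count, dtype=np.int64)
            else:
                r = self.dispersion
                p = r / (r + self.mean)
                values = self.min_count + rng.negative_binomial(r, p, size=n)
                if self.contamination > 0:
                    tail = rng.random(n) < self.contamination
                    if tail.any():
                        values[tail] += rng.poisson(
                            self.contamination_scale * max(self.mean, 1.0),
                            size=int(tail.sum()),
                        )
        else:
            values = _symmetric_sample(self.center, self.half_width, n, rng)
        return np.maximum(values + self.shift, 0)


def _symmetric_sample(
    center: int, half_width: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """A multiset symmetric around ``center`` whose extremes are forced to
    ``center ± half_width``: median == center and range == 2*half_width
    exactly (for n >= 2)."""
    if n == 1:
        return np.array([center], dtype=np.int64)
    values = [center - half_width, center + half_width]
    remaining = n - 2
    deltas = rng.integers(0, half_width + 1, size=remaining // 2)
    for delta in deltas:
        values.extend((center - int(delta), center + int(delta)))
    if remaining % 2:
        values.append(center)
    return np.array(values, dtype=np.int64)


LawSpec = CountLaw | Mapping[str, CountLaw]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generator.

    ``thorax_law`` / ``pygidium_law`` may be a single :class:`CountLaw`
    (shared by every bin) or a mapping bin -> law.  ``family_mode``:
    ``none`` draws species independently; ``clustered`` draws one latent
    location per family and concentrates species around it with standard
    deviation ``family_effect_sd``; ``range_locked`` gives every family a
    symmetric-range law of its own (requires a symmetric_range thorax law).
    """

    n_per_bin: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_BIN)
    )
    thorax_law: LawSpec = field(default_factory=CountLaw)
    pygidium_law: LawSpec = field(
        default_factory=lambda: CountLaw(min_count=1, mean=6.0, dispersion=1.5)
    )
    n_families_per_order: int = 3
    family_mode: str = "none"
    family_effect_sd: float = 1.0
    enrolment_mix: Mapping[str, Mapping[str, float]] | None = None
    enrolment_thorax_shift: Mapping[str, int] | None = None
    orders: tuple[str, ...] = ORDERS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_bin:
            raise ConfigError("n_per_bin must not be empty")
        for bin_label, n in self.n_per_bin.items():
            if bin_label not in PERIODS:
                raise ConfigError(f"unknown time bin {bin_label!r}")
            if n < 1:
                raise ConfigError(f"sample size for {bin_label} must be >= 1")
        if self.family_mode not in FAMILY_MODES:
            raise ConfigError(f"family_mode must be one of {FAMILY_MODES}")
        if self.n_families_per_order < 1:
            raise ConfigError("n_families_per_order must be >= 1")
        if self.family_effect_sd < 0:
            raise ConfigError("family_effect_sd must be >= 0")
        if self.enrolment_mix is not None:
            for bin_label, mix in self.enrolment_mix.items():
                total = sum(mix.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"enrolment probabilities for {bin_label} sum to {total}, not 1"
                    )

    def law_for(self, which: str, bin_label: str) -> CountLaw:
        spec = self.thorax_law if which == "thorax" else self.pygidium_law
        if isinstance(spec, CountLaw):
            return spec
        try:
            return spec[bin_label]
        except KeyError as exc:
            raise ConfigError(f"no {which} law for bin {bin_label!r}") from exc


@dataclass(frozen=True)
class ScenarioPreset:
    """A named generator scenario with parameter overrides."""

    name: str
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# generation


def _family_names(order: str, n_families: int) -> list[str]:
    return [f"{order}_fam{i + 1}" for i in range(n_families)]


def _draw_thorax(
    config: SyntheticConfig,
    law: CountLaw,
    families: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = families.size
    if config.family_mode == "none":
        return law.sample(n, rng)
    values = np.empty(n, dtype=np.int64)
    for fam in np.unique(families):
        mask = families == fam
        m = int(mask.sum())
        if config.family_mode == "clustered":
            latent = law.sample(1, rng)[0]
            noise = np.rint(rng.normal(0.0, config.family_effect_sd, size=m)).astype(
                np.int64
            )
            values[mask] = np.maximum(latent + noise, 0)
        else:  # range_locked
            if law.base != "symmetric_range":
                raise ConfigError("family_mode='range_locked' needs a symmetric_range law")
            offset = int(rng.integers(-2, 3))
            values[mask] = _symmetric_sample(
                law.center + law.shift + offset, law.half_width, m, rng
            )
    return values


def generate_dataset(config: SyntheticConfig) -> list[SegmentRecord]:
    """Generate one species-level dataset.

    Counts are integers >= 0 with thorax + pygidium >= 1; family labels are
    nested within orders; enrolment labels follow the per-bin mix when one
    is configured.  Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SegmentRecord] = []
    species_counter = 0
    bins = [p for p in PERIODS if p in config.n_per_bin]
    for bin_label in bins:
        n = config.n_per_bin[bin_label]
        order_idx = rng.integers(0, len(config.orders), size=n)
        orders = np.array(config.orders)[order_idx]
        family_idx = rng.integers(0, config.n_families_per_order, size=n)
        families = np.array(
            [f"{o}_fam{i + 1}" for o, i in zip(orders, family_idx)], dtype=object
        )

        thorax = _draw_thorax(config, config.law_for("thorax", bin_label), families, rng)
        pygidium = config.law_for("pygidium", bin_label).sample(n, rng)

        if config.enrolment_mix is not None and bin_label in config.enrolment_mix:
            mix = config.enrolment_mix[bin_label]
            types = list(mix)
            enrolment = rng.choice(types, size=n, p=[mix[t] for t in types])
        else:
            enrolment = np.full(n, None, dtype=object)

        if config.enrolment_thorax_shift:
            for strategy, shift in config.enrolment_thorax_shift.items():
                mask = enrolment == strategy
                thorax[mask] = np.maximum(thorax[mask] + shift, 0)

        # the trunk must exist
        empty = (thorax + pygidium) == 0
        pygidium[empty] = 1

        for i in range(n):
            species_counter += 1
            records.append(
                SegmentRecord(
                    species_id=f"sp{species_counter:05d}",
                    order_name=str(orders[i]),
                    family_name=str(families[i]),
                    period=bin_label,
                    thorax=int(thorax[i]),
                    pygidium=int(pygidium[i]),
                    enrolment=None if enrolment[i] is None else str(enrolment[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# presets


def _uniform_mix() -> dict[str, dict[str, float]]:
    share = 1.0 / len(ENROLMENT_TYPES)
    return {p: {t: share for t in ENROLMENT_TYPES} for p in PERIODS}


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Build the :class:`SyntheticConfig` for a named scenario.

    ``pygidium_trend`` accepts ``shift`` (default 3, applied to the last
    bin's pygidium law) and ``n_per_bin``.
    """
    if name == "global_null":
        config = SyntheticConfig(
            thorax_law=CountLaw(min_count=2, mean=8.0, dispersion=1.5, contamination=0.03),
            pygidium_law=CountLaw(min_count=1, mean=6.0, dispersion=1.5, contamination=0.03),
            enrolment_mix=_uniform_mix(),
            seed=seed,
        )
    elif name == "pygidium_trend":
        shift = int(overrides.pop("shift", 3))
        n_per_bin = overrides.pop("n_per_bin", {p: 100 for p in PERIODS})
        base = CountLaw(min_count=1, mean=6.0, dispersion=20.0)
        laws = {p: base for p in PERIODS}
        laws["Permian"] = replace(base, shift=shift)
        config = SyntheticConfig(
            n_per_bin=n_per_bin,
            thorax_law=CountLaw(min_count=2, mean=8.0, dispersion=20.0),
            pygidium_law=laws,
            seed=seed,
        )
    elif name == "range_contraction":
        half_widths = {p: hw for p, hw in zip(PERIODS, (8, 7, 6, 5, 4, 3))}
        config = SyntheticConfig(
            n_per_bin={p: 60 for p in PERIODS},
            thorax_law={
                p: CountLaw(base="symmetric_range", center=10, half_width=hw)
                for p, hw in half_widths.items()
            },
            pygidium_law=CountLaw(min_count=1, mean=6.0, dispersion=2.0),
            seed=seed,
        )
    elif name == "family_conservation":
        half_widths = {p: hw for p, hw in zip(PERIODS, (6, 5, 4, 3, 2, 1))}
        config = SyntheticConfig(
            n_per_bin={p: 80 for p in PERIODS},
            thorax_law={
                p: CountLaw(base="symmetric_range", center=12, half_width=hw)
                for p, hw in half_widths.items()
            },
            pygidium_law=CountLaw(min_count=1, mean=6.0, dispersion=2.0),
            family_mode="range_locked",
            n_families_per_order=2,
            seed=seed,
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; expected one of {PRESETS}")
    if overrides:
        config = replace(config, **overrides)
    return config


def preset(name: str, seed: int = 0, **overrides) -> ScenarioPreset:
    return ScenarioPreset(name=name, config=preset_config(name, seed, **overrides))


def generate_fixture(name: str, seed: int, out_path) -> str:
    """Write the CSV for a named preset; byte-identical per (name, seed)."""
    records = generate_dataset(preset_config(name, seed))
    write_dataset(records, out_path)
    return str(out_path)
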