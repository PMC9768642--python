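# segtrends

Statistical analysis of long-term trends in trilobite trunk segmentation:
per-species counts of thoracic tergites and pygidial segments are compared
across Palaeozoic time bins with permutation tests for median location
shifts under strong familywise error control, plus the accompanying
sensitivity analyses (leave-one-taxon-out jackknife, rarefaction of
ranges, within-family range trends, enrolment-strategy subsets) and a
synthetic-data generator that reproduces the statistical structure of the
real data (skewed, heavy-tailed count distributions with unequal sample
sizes and family-level clustering).

## What is in the box

| module | purpose |
| --- | --- |
| `segtrends.io_dataset` | data model, CSV reading/validation, derived variables (trunk = T + P, pygidial proportion = P / (T + P)), grouping |
| `segtrends.median_permutation` | single-step max-statistic permutation test for pairwise median differences, step-down (conservative maximal subsets) variant, exact enumeration oracle, moment diagnostics |
| `segtrends.synthetic_data` | seeded generator with scenario presets: `global_null`, `pygidium_trend`, `range_contraction`, `family_conservation` |
| `segtrends.trend_pipeline` | timescale analyses, jackknife, rarefied ranges, within-family ranges, enrolment analyses, `run_all` orchestrator with a reproducible JSON manifest |
| `segtrends.cli_report` | `segtrends` CLI, matrix-style significance tables, distribution summaries |

## Command line

```sh
# make a synthetic dataset
segtrends simulate --preset global_null --seed 1 --out data.csv

# all-pairs median tests per variable across periods
segtrends run --data data.csv --timescale period \
    --variables thorax,pygidium,trunk,proportion \
    --permutations 10000 --seed 1 --alpha 0.05 --out results/

# sensitivity analyses
segtrends jackknife --data data.csv --grouping order --out results/
segtrends rarefy --data data.csv --iterations 1000 --out results/rarefaction.csv
segtrends family-ranges --data data.csv --out results/family_ranges.csv
segtrends enrolment --data data.csv --out results/

# everything, with a JSON run manifest
segtrends run-all --data data.csv --seed 1 --out results/
```

All results are CSV (plus a markdown matrix and a JSON manifest); logs go
to stderr. Exit codes: 0 success, 1 configuration error, 2 data error.

Input CSVs need columns `species, order, family, period, thorax` and
optionally `series, pygidium, enrolment`; arbitrary headers can be mapped
via `segtrends.io_dataset.read_dataset(path, schema={...})`. Records with
a missing pygidium count stay in thorax-only analyses and are excluded
from pygidium/trunk/proportion analyses.

## Statistical notes

* The test statistic is the unstudentized absolute difference of group
  medians; all pairwise hypotheses are referred to the permutation
  distribution of the **maximum** pairwise difference (single-step), which
  controls the familywise error rate strongly without assuming normality
  or equal sample sizes.
* Monte Carlo p-values use the add-one convention `(1 + count) / (B + 1)`
  and are therefore never zero; the default number of permutations is
  10 000.
* The step-down variant retests hypotheses in decreasing order of the
  observed statistic against max-statistic nulls restricted to the
  maximal group subsets still consistent with the not-yet-rejected
  hypotheses, taking the most conservative candidate p and enforcing
  monotonicity, so it is uniformly at least as powerful as the
  single-step test on the same permutation stream.
* Medians of even-sized groups are midpoints of the central order
  statistics; quartiles use linear interpolation; ties are left as-is.
* Sequential (adjacent-bin) tables are extracted from the single
  all-pairs analysis, never re-tested.
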