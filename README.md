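# discrindex

Quantifying how much tighter pandemic-response restrictions were for
**non-vaccinated** people than for **vaccinated** people, per country and
per day, from differentiated policy-tracker panels.

During 2021–2022 many governments coded their COVID-19 containment and
health policies (school closing, workplace closing, gathering limits,
facial coverings, ...) as daily ordinal indicators, and — once vaccine
passes appeared — recorded separate values for vaccinated and
non-vaccinated residents. `discrindex` turns such panels into a
country-level **discrimination index** and runs the full downstream
analysis: per-country summaries, top-10 rankings, the zero-discrimination
partition, continental/sub-regional grouping, equal-interval map
classification, and daily timeline tables. A synthetic panel generator
with a closed-form oracle makes the entire pipeline verifiable without
any external data.

## The metric

Each indicator *j* with ordinal code *v<sub>j</sub>* ∈ {0, …, N<sub>j</sub>}
and geographic-scope flag *f<sub>j</sub>* (1 = nationwide, 0 = regionally
targeted) is normalized to a 0–100 sub-index:

```
I_j = 0                                   if v_j = 0
I_j = 100 · (v_j − 0.5·(1 − f_j)) / N_j   if indicator j is flagged
I_j = 100 · v_j / N_j                     otherwise
```

A composite index is the unweighted mean of its members' sub-indices —
14 indicators (C1–C8, H1, H2, H3, H6, H7, H8) for the Containment and
Health Index (CHI), 9 (C1–C8, H1) for the Stringency Index. Computing the
composite separately for the two status groups (a differentiated
indicator contributes its group-specific code where one exists, the
shared code otherwise) gives CHI<sub>NV</sub>(t) and CHI<sub>V</sub>(t),
and the daily discrimination index is

```
D(t) = CHI_NonVaccinated(t) − CHI_Vaccinated(t)
```

on the stacked 2021-01-01 … 2022-12-31 axis (730 days). Countries are
summarized by the mean, median and maximum of D — the mean combines
duration and magnitude, the median is typically 0 because differentiation
started mid-period.

## Worked example

The built-in synthetic fixture set ships 14 country profiles across five
continents with known injected discrimination episodes:

```sh
discrindex rank --synthetic --by mean_D --top 5
```

```
 rank country_code country_name  mean_D
    1          PAK     Pakistan   14.29
    2          AZE   Azerbaijan   13.41
    3          RWA       Rwanda   12.91
    4          FJI         Fiji   10.44
    5          MAR      Morocco    8.22
```

`mean_D` is each country's discrimination index averaged over all 730
days: the top country here held restrictions on the non-vaccinated about
14 index points above those on the vaccinated, averaged across the whole
two-year window (its daily peak is 35.71). The same run's
zero-discrimination partition:

```sh
discrindex partition --synthetic
```

```
zero-discrimination countries: 2 (mean index 47.83)
discriminated countries:       12 (mean index 44.67)
zero set: CHN, TZA
```

Two profiles never differentiate by vaccination status (one with a very
high underlying CHI, one very low), so they fall into the zero set; the
"mean index" columns compare the average underlying CHI between the two
groups of countries.

The same analysis runs on real archived panel CSVs:

```sh
discrindex compute --input-2021 panel_2021.csv --input-2022 panel_2022.csv \
    --regions countries_by_continent.csv --basis chi --out-dir out/
```

or, in Python:

```python
import discrindex as dx

bundle = dx.run_pipeline(dx.PipelineConfig(
    input_2021="panel_2021.csv", input_2022="panel_2022.csv",
    regions_path="countries_by_continent.csv", basis="CHI",
    source="published",   # use the panel's shipped index columns
))
bundle.ranking_mean       # top-10 by average discrimination
bundle.partition          # zero vs non-zero countries + mean CHI of each
bundle.classified_mean    # 5 equal-interval classes over [0, 20]
```

## Package layout

| module | contents |
|---|---|
| `discrindex.codebook` | indicator coding schema, flags, index memberships |
| `discrindex.oxcgrt_io` | wide-panel dialect reader/writer, region list, tidy CSV |
| `discrindex.index_engine` | sub-index formula, composite indices per status group |
| `discrindex.discrimination` | daily D(t), year stacking, study window |
| `discrindex.aggregation` | country summaries, rankings, partition, OLS associations |
| `discrindex.synthetic` | profile-based panel generator + closed-form oracle |
| `discrindex.reporting` / `cli` | equal-interval classes, timelines, pipeline, CLI |

See `docs/methods.md` for the modelling notes and design choices.
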