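# Methods

## The measurement model

The package treats government pandemic-response policy as a panel of daily
ordinal indicator codes per country. Fourteen containment-and-health
indicators are modelled (C1–C8, H1, H2, H3, H6, H7, H8), each with a
maximum code N_j between 2 and 5 and, for most, a binary geographic-scope
flag (1 = nationwide, 0 = targeted to a specific region). The sub-index
normalization

    I_j = 100 · (v_j − 0.5·(1 − f_j)) / N_j   (0 when v_j = 0)

maps each code to a 0–100 scale, deducting half a code step for regional
targeting as a crude correction for the convention that the panel records
the strictest policy found anywhere in the country. Composite indices are
unweighted means over their member sub-indices: 14 members for the
Containment and Health Index (CHI), 9 (C1–C8 and H1) for the Stringency
Index. Equal weighting is an assumption inherited from the index design,
not a claim that a school closure and a masking rule are equally
consequential.

Ten indicators (C1–C8, H6, H8) may carry separate values for vaccinated
and non-vaccinated people. The composite index for status group g uses
the g-specific observation for a differentiated indicator on days when
one exists and the shared value otherwise; non-differentiated indicators
contribute identically to both groups. The discrimination index is the
pointwise difference

    D(t) = Index_NonVaccinated(t) − Index_Vaccinated(t),

bounded in [−100, 100]. D is expected non-negative in practice (no
jurisdiction is known to have restricted the vaccinated more), but
negative values are preserved and logged rather than clipped, because the
definition does not forbid them and clipping would silently hide data
problems.

The study window is the closed interval 2021-01-01 to 2022-12-31 — 730
days, no leap day — chosen to cover the vaccine-pass era. Annual series
are stacked onto one continuous axis; overlaps or gaps at the year
boundary are hard errors. Per-country summaries (mean, median, maximum of
D) are computed over *all* 730 days, including the pre-differentiation
stretch of zeros. That denominator choice is deliberate: the mean then
measures the combination of magnitude and duration, and the median of a
country that differentiated for less than half the window is 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `basis` | `CHI` | composite index used for D; `STRINGENCY` yields systematically higher values because the differentiated C indicators make up 8 of its 9 members rather than 10 of 14 |
| `source` | `recomputed` | recompute indices from indicator codes; `published` uses the panel's shipped index columns (the original analysis path for archived data) |
| `strict` | `True` | a country-day missing a member indicator is an error; permissive mode averages the present members and logs |
| `classes`, `mean_domain`, `max_domain` | 5, [0, 20], [0, 40] | equal-interval choropleth classification; domains are fixed per map so class colours are comparable across countries — out-of-domain values error rather than clip, and a Stringency-basis run generally needs wider domains |
| `h7_flag` (codebook) | `True` | H7's companion variable records cost rather than geographic scope; it is treated as a flag in sub-index arithmetic to match the upstream index calculation, and can be disabled |

## Numerical choices

* Sub-index and composite arithmetic is exact IEEE-754 double arithmetic;
  values are rounded to 2 decimals only at export boundaries (tidy CSVs,
  published index columns), matching how such panels ship their index
  columns.
* The engine and the synthetic oracle both average member scores with
  `np.mean` over the members in fixed codebook order, so the two code
  paths (vectorized matrix vs scalar per-day evaluation) agree bit-for-bit
  — the end-to-end recovery tests assert exact equality, no tolerance.
* A positive code whose flag cell is empty is scored as regionally
  targeted (flag 0) with a logged warning; this follows the deduction
  convention for the nationwide flag being unset and only arises in real
  archives during pre-differentiation blanks, never in generated data.
* Ranking ties are broken by ISO alpha-3 code so rankings are
  reproducible; associations use the standard OLS slope test
  (`scipy.stats.linregress`), with a constant response reported as R² = 0
  and a constant predictor rejected as an undefined fit.
* Equal-interval classes are right-closed, with the first class also
  containing the lower domain bound; the boundary ratio is rounded at the
  9th decimal to keep exact boundary values (e.g. 8.0 on a width-4 grid)
  in the lower class despite float noise.

## The synthetic generator, and what it does not emulate

`discrindex.synthetic` generates panels from country profiles: a
per-indicator baseline (constant or step function) applied to everyone,
plus episodes during which the non-vaccinated group receives extra
ordinal steps (clamped at N_j) on chosen differentiated indicators while
the vaccinated group keeps the baseline. Generated panels use the same
wide-CSV dialect as archived national files — status-variant column
infixes, `_Flag` companions, 8-digit dates, pre-computed index columns —
so the reader, the index engine and the published-column path are all
exercised end to end. Because each profile is closed-form, expected index
and discrimination values are computable without the panel
representation, giving exact oracles for recovery tests.

The default fixture set holds 14 profiles across five continents with
onsets from January 2021 to March 2022 and magnitudes from a single mild
indicator to broad multi-indicator regimes, including one regionally
targeted (flag 0) episode, one clamped delta, and two countries that
never differentiate (one high-baseline, one low-baseline) so the
zero-discrimination partition and its CHI comparison are non-trivial. All
fixtures are deterministic; randomness exists only in optional onset
jitter and in the fuzzing generator, both driven by an explicit seed.

What the generator does **not** emulate: epidemiological dynamics (cases,
deaths, vaccination coverage), policy autocorrelation beyond step
functions, data-entry noise, revisions, or missing cells. Passing the
recovery tests therefore demonstrates that the pipeline's arithmetic and
plumbing are correct, not that real archives are clean; on real data the
published-column path and the strict/permissive switches exist precisely
because archives contain blanks the generator never produces.

Problem sizes: tests and the acceptance script run the full 730-day,
14-country fixture pipeline once, and fuzz invariants over 1000 random
profiles on 30-day windows — small enough to keep the whole suite in the
tens of seconds while covering every code path.

## Design choices where the design was open

* **Which CHI underlies `mean_CHI`.** Per-country "underlying average
  CHI" uses the non-vaccinated-basis series over the full window. For
  zero-discrimination countries every choice (NV, V, average) coincides;
  for the rest the NV series represents the restrictions actually faced
  by the group the metric is about.
* **Column dialect.** All wide-panel column-name knowledge lives in one
  `PanelDialect` object (regex for indicator/variant/flag columns, named
  index columns); alternate archive layouts are a dialect instance away,
  and unknown indicator-like columns are warned about and skipped rather
  than guessed at.
* **Continent vocabulary.** The region reader warns on but retains
  continents outside the usual six (a UNSD-derived list may contain
  Antarctica); join mismatches are surfaced in an `unmatched` report
  instead of being dropped, since analysis-worthy jurisdictions (e.g.
  Kosovo) are routinely absent from standard lists.
* **Missing codes at I/O time** stay absent rather than being imputed to
  0; completeness ("all indicators start at 0") is a property of the
  generator and of well-formed archives, enforced downstream by strict
  mode, not silently manufactured by the reader.

## Known limitations

* The index differences weight all member indicators equally; D is a
  cursory magnitude-times-breadth measure, not a severity-weighted one —
  any re-weighting would require normative judgements the package
  deliberately avoids.
* Panels record policy enactment, not enforcement, and national codes
  hide subnational variation beyond the 0.5 flag deduction.
* The Stringency-basis maps need different classification domains than
  the CHI basis; defaults target the CHI.
* Display smoothing used by some published index variants is not
  implemented; all series are plain daily values.
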