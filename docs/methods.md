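# Methods

## Cohort construction

The unit of analysis is the unique investigator, defined as a unique
(last name, first name) key among Form 1572 submission records. Keys are
normalized before matching — surrounding whitespace trimmed, internal
whitespace runs collapsed, case folded — because registry entries for the
same person routinely differ in casing and spacing. Normalization can be
switched off (`normalize=False` / `--no-normalize`) for strict raw-string
matching. Name-keyed deduplication has a known failure mode in both
directions: distinct people sharing a name collapse into one history, and
a person whose entries differ beyond normalization splits into several.
No record linkage beyond the name key is attempted; the synthetic
generator's `name_collision_rate` knob exists to measure the first bias.

Records are first restricted to the study window (receipt-date **year**
within [start, end], 1999–2015 by default) and records whose normalized
last name is empty or `"??"` are excluded with a reported count. Within an
investigator, submissions are sorted by receipt date with ties broken by
original file order (stable sort); a same-day second submission therefore
yields a gap of 0 days, which is a valid stayer gap. The derived variables
are:

| variable  | definition                                                | unit |
|-----------|-----------------------------------------------------------|------|
| `newid`   | dense id per name key, in order of first appearance       | –    |
| `obs`     | 1-based submission index within an id                     | –    |
| `firsub`  | earliest receipt date; the year an investigator counts in | date |
| `secdiff` | days from first to second submission; absent if single    | days |
| `oad`     | exactly one submission in the window                      | flag |

Location is binary: US iff the trimmed, case-folded country of the **first**
submission equals `"usa"`; every other value, including missing, is non-US
(missing and conflicting countries are logged). The first submission decides
because the investigator is attributed to `firsub` everywhere else too.

## Phenotype classification

Multi-submission investigators contribute their `secdiff` to an empirical
gap distribution; the cutoff is its nearest-rank percentile — the
⌈p/100·n⌉-th order statistic — so the cutoff is always an observed gap
value. `p = 75` by default; linear interpolation is available via
`method="linear"`. Labels:

- single submission → **one-and-done**;
- `secdiff ≤ cutoff` → **stayer** ("within" the percentile is read as ≤);
- `secdiff > cutoff` → **stop-and-go**.

The ≤/>, nearest-rank choices make the three classes an exact partition and,
when gaps are untied, force the stayer share among multi-submission
investigators to ⌈0.75·n⌉/n ≈ 75% by construction — a useful internal check,
not an empirical finding. Raising the percentile can only move investigators
from stop-and-go to stayer (monotonicity), and `p = 100` leaves no
stop-and-go at all.

The cutoff is recomputed from the cohort being classified by default;
`fixed_cutoff_days` (e.g. 1013) supports replaying a previously derived
cutoff against new data. A degenerate cohort with no multi-submission
investigators is labeled all one-and-done without computing a threshold.
Third and later submissions are kept in the history but never influence
`secdiff`, the threshold, or the label.

## Trend tables and reporting

Each investigator appears in exactly one trend-year, the year of `firsub`.
The long-format table covers every (year × phenotype × location) cell of
the window, zeros included, with two shares: the cell's fraction of that
year's new investigators, and the location split within the (year,
phenotype) cell. Printed percentages are 100·num/den rounded **half-up**
to one decimal (via `decimal.Decimal`, not banker's rounding), matching
registry-report convention; this is why reported phenotype percentages sum
to 100.0 only within ±0.1.

## Synthetic registry generator

The generator draws, per simulated person: a Bernoulli(`frac_single`)
single/multi indicator, a Bernoulli(`frac_us`) location, a first-submission
date uniform over the arrival window, and — for multi persons — an integer
gap from the configured distribution, plus Poisson(`extra_submission_rate`)
later submissions that downstream code must ignore. A planned second
submission falling after December 31 of `window_end` is dropped and the
person marked censored. Invalid-name noise records (`"??"`/empty last name)
are injected at `invalid_name_rate` × the person-record count, and a
`name_collision_rate` fraction of people reuse an earlier person's name key.
Record order is a seeded permutation; the whole stream is deterministic
given the config seed.

Defaults: 20,000 investigators, `frac_single = 0.5`, `frac_us = 0.6`,
window 1999–2015 with uniform arrivals, 1% invalid-name noise, no name
collisions, and a lognormal gap distribution parameterised by its median
(411 days) and 75th percentile (1013 days), i.e. μ = ln 411,
σ = ln(1013/411)/z₀.₇₅ ≈ 1.337. These mirror the documented study
conditions where stated (window, gap quantiles, ballpark one-and-done
share); the US share and noise rate are undocumented in the source
registry and were fixed once at field-plausible values.

Ground truth is per person, not per name key: the phenotype each person
would receive in an uncensored, collision-free regime (using the
nearest-rank 75th percentile of all drawn gaps as the truth cutoff), their
location, and the censoring flag.

What the generator does **not** emulate: realistic name demographics and
typos (collisions are exact key reuse), non-uniform arrival intensity
(the real registry's yearly totals decline), country-field free-text noise,
and any sponsor-level submission correlation. Passing recovery tests
therefore shows the pipeline is correct under the stated mixture model,
not that the name key or the binary country rule are unbiased on the real
registry.

## Censoring experiment

`censoring_experiment` runs the full pipeline on a generated cohort and,
joining pipeline labels back to persons by name key (collisions forced off
to keep the join exact), reports per first-submission year the fraction of
truly multi-submission people labeled one-and-done because the window
truncated their second submission. With lognormal gaps and uniform
arrivals this fraction is near zero early and rises steeply in the final
years — the mechanism behind late-window inflation of one-and-done counts,
and the reason observed gap quantiles computed inside the window sit below
the generator's asymptotic 411/1013 days.

## Numerical and I/O choices

- Dump dialect: `|`-delimited, header row, UTF-8 with a logged Latin-1
  fallback, dates tried as ISO `YYYY-MM-DD` then `MM/DD/YYYY`. All are
  configurable (`DumpDialect`), including headerless index-based column
  maps; the default is a documented convention for the package's own
  dumps, not a claim about any particular registry export.
- Malformed rows are rejected with row number and reason, never silently;
  if more than half of the data rows reject, the read aborts, since that
  pattern almost always means a wrong dialect rather than dirty data.
- Problem sizes: tests classify cohorts of up to 20,000 investigators and
  the acceptance script uses 8,000–20,000; at these sizes every stage runs
  in seconds and binomial/quantile sampling error is small relative to the
  stated tolerances (the sample 75th percentile of the default lognormal
  has a standard error of ~24 days at 8,000 gaps).

## Known limitations

- The name key inherits all the ambiguity of names; homonym collapse is
  quantifiable with the collision knob but not corrected.
- Location is first-submission country only; investigators who relocate
  are fixed at their entry location.
- The percentile cutoff is cohort-relative: classifications from different
  windows or subsets are not directly comparable unless a fixed cutoff is
  supplied.
- No statistical trend testing is provided; the trend tables are
  descriptive counts and shares.
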