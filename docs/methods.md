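# Methods

## The analysis model

`jadersig` implements frequentist disproportionality analysis over a
spontaneous adverse-event reporting database distributed as linked CSV
tables: a drug table (one row per drug per report, with a role field)
and a reaction table (one row per adverse event per report, named by a
MedDRA Preferred Term), joined by a case identification number.

The analysis unit is the **drug–event pair**: a unique
(case, suspected drug, PT) triple. When a report lists several
suspected drugs, each is treated as a separate adverse-reaction report;
the same drug/PT combination is counted at most once per case.
Concomitant and interacting drugs are excluded before linking so every
pair carries the reporter's judgement of association. Duplicate report
versions are resolved before linking by keeping each case's highest
version number (later report iterations supersede earlier ones); a
`first_seen` strategy is available for sensitivity analysis.

The grand total N of pairs defines the margins of each per-(drug, PT)
2×2 table with cells

|              | target PT | other PTs |
|--------------|-----------|-----------|
| target drug  | a         | b         |
| other drugs  | c         | d         |

and three indexes:

- ROR = ad/bc, 95% Wald CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
- PRR = [a/(a+b)] / [c/(c+d)];
- χ²: Pearson 2×2 statistic, Yates-corrected by default,
  N(|ad−bc|−N/2)² / [(a+b)(c+d)(a+c)(b+d)], the subtraction floored
  at zero.

A pair is a **signal** only when (a) the ROR CI lower bound exceeds 1
*and* (b) PRR ≥ 2, χ² ≥ 4 and n = a ≥ 3. All four thresholds are
configuration, defaulting to these conventional values. Signals are
hypothesis-generating flags, not evidence of causality.

## Numerical choices

- The CI critical value is fixed at exactly 1.96 rather than obtained
  from a quantile routine, so outputs are bit-stable across platforms.
- Degenerate tables make a statistic *undefined* (NaN), never an
  exception: a zero cell for the ROR, an empty drug margin or zero
  comparator cell for the PRR, an empty margin for χ². An undefined
  metric fails its criterion. Since n ≥ 3 already excludes a = 0, this
  policy cannot hide a true signal. A Haldane–Anscombe +0.5 adjustment
  is available for exploratory output only; the verdict always uses
  the raw cells.
- The χ² variant defaults to Yates-corrected because the
  PRR ≥ 2 / χ² ≥ 4 / n ≥ 3 triple descends from criteria defined on
  the corrected statistic; the plain Pearson form is one flag away,
  and both are exercised against independent oracles in the tests.
- Metrics are computed only for drugs actually co-reported with the
  PT (a ≥ 1); drugs with a = 0 are omitted rather than emitted as
  non-signals. Output ordering is deterministic: query order, then
  descending a, then drug name (report-table ordering conventions vary
  between published analyses, so we fix one).
- Drug identity is the exact ingredient-name string after NFKC
  normalization, trimming and case folding. Public dumps do not
  separate brand and generic products, and no synonym resolution is
  attempted beyond an optional user map.
- Report TSVs print floats at 4 significant digits; the JSON sidecar
  keeps full precision.

## Classification stage

Signal drugs are grouped by the Japanese commodity-classification
3-digit therapeutic category codes, supplied as a user CSV (the
official list is not redistributable here); codes beginning "42"
(antineoplastic agents) are excluded so appetite and taste events
attributable to the malignancy itself do not masquerade as drug
signals. The exclusion is applied after detection, and both the kept
and excluded lists are written, so either reading of the flow is
recoverable. Drugs missing from the map are routed to an explicit
review list, never silently dropped. Package-insert annotation is also
a user-supplied table of explicit booleans per drug; drugs absent from
it are reported as unreviewed rather than defaulted.

## Synthetic-report generator

The generator emulates the data model the pipeline consumes: cases
with a zero-truncated-Poisson number of drug records drawn from a
popularity-weighted catalog, per-record roles from a configurable mix,
PT events occurring independently per case at background rates, known
duplicate report versions, and *planted* drug–event associations where
the event probability is p1 when the case carries the drug as
suspected and p0 otherwise (implied OR = [p1/(1−p1)]/[p0/(1−p0)]).

Design choices that matter:

- **Within-case drug draws are with replacement.** Repeat draws become
  distinct `drug_seq` rows of the same drug — which real tables also
  contain, and which the pair-uniqueness rule must collapse — and the
  inclusion probability P(case carries drug D as suspected | k draws)
  gets the closed form 1−(1−w_D·r_s)^k. That makes `planted_truth` an
  exact, sampling-free function of the configuration; weighted
  sampling without replacement has no comparable closed form.
- **Every case has ≥ 1 reaction row** (a report exists because
  something was observed). A case that would otherwise be event-free
  receives one fallback event drawn from the *non-planted* PTs in
  proportion to their background rates, so planted odds ratios are
  never diluted. Consequently each planted PT may appear in only one
  planted association, the planted p0 overrides that PT's catalog
  rate, and at least one non-planted PT must exist.
- PT occurrences are independent across PTs given the drug set —
  adequate for testing per-(drug, PT) marginal statistics, which is
  all this pipeline computes.
- Duplicates are exact copies with an incremented version number, so
  deduplication must restore the original case count exactly; the
  truth registry records it.

What the generator does **not** emulate: demographics, dates and
outcomes; reporting waves and stimulated-reporting bursts;
masking/competition bias from dominant drugs or events; name variants
needing synonym resolution; within-case correlation between PTs.
Passing recovery tests therefore demonstrates correctness of the
counting and the estimators under the stated sampling model — not
robustness to the reporting biases of real spontaneous data.

## Preset study conditions

Three presets fix the simulated populations used by the test suite and
the acceptance script:

- `nutrition_default_config`: 2,000 cases; 20 drugs with Zipf(1)
  popularity weights, two of them antineoplastic (category 421); the
  seven nutrition-related target PTs at background rates 0.002–0.010
  plus five common background PTs (0.02–0.08); roles
  55/40/5% suspected/concomitant/interacting; λ = 1 drugs per case
  (zero-truncated); 10% duplicated cases; two planted associations
  (OR 8 on Decreased appetite, OR 6 on Dysgeusia). Rates were chosen
  once so that target-PT pair counts land in the tens — the regime
  where the composite criterion's n ≥ 3 floor is actually exercised.
- `single_association_config`: 5,000 cases, suspected-only roles,
  λ = 0.05 (≈ one drug per case), one planted pair with p0 = 0.01 and
  p1 set from the requested odds ratio, the planted drug's weight
  sized so the expected a cell hits a requested value (20 at OR 5,
  30 at OR 10). Near-single-drug reports keep co-suspected-drug
  contamination of the comparator cell below ~1%, isolating the
  estimator; this is the configuration for CI-coverage and
  parameter-recovery measurements.
- `all_null_config`: 2,000 cases, no planted pairs, rates chosen so
  ~50 (drug, PT) combinations have expected a ≥ 3 and qualify as
  false-positive candidates.

Monte-Carlo scales: 200 replicates for CI coverage / recovery, 100 for
sensitivity and the null false-positive rate, with binomial standard
errors reported alongside each rate.

## Pipeline and reproducibility

The orchestrated run is load → dedup → filter → link → extract →
detect → classify → report. Every stage count is recorded in a
manifest sufficient to redraw the flow chart, the full configuration
is echoed into the output directory, and reruns on identical inputs
produce byte-identical outputs (no unseeded randomness exists anywhere
in the analysis path). Intermediate caching was deliberately left out:
the pipeline is deterministic and desk-scale reruns take seconds, so
content-hash caches would add invalidation risk without benefit;
re-running detection under new thresholds is served by the `detect`
subcommand reading the saved pair-universe TSV.

Open points the implementation exposes as configuration rather than
deciding silently: whether the pair universe counts distinct triples
or raw joined rows (`unit: triple | row`; triple is the default and the
documented convention); whether PT matching is by code, name or either
(either by default — public reaction tables carry names, codes come
from the user's query file); χ² variant; dedup strategy.

## Known limitations

- Counts reflect reporting, not incidence; no denominator exists.
- No Bayesian shrinkage (IC/BCPNN, EBGM), no time-to-onset, no
  age/sex stratification.
- No MedDRA hierarchy expansion: PT query sets are flat lists under
  the user's control.
- The Wald CI is asymptotic; for very small a its coverage relies on
  the n ≥ 3 floor and is verified empirically only under the preset
  study conditions.
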