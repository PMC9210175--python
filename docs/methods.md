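# Methods

`inclusion-monitor` implements an individual-level pipeline for monitoring
the social inclusion of people with disabilities from survey microdata.
This note documents the model, the defaults and why they were chosen, the
numerical decisions, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Severity classification

**Disability.** Disability status is derived from the Washington Group
Short Set (WG-SS): six functioning domains (seeing, hearing, walking,
cognition, self-care, communication), each on a four-level ordinal scale
(`no_difficulty < some_difficulty < a_lot_of_difficulty <
cannot_do_at_all`). The default rule classifies a respondent as

* **none** — at most one `some_difficulty`, nothing above it;
* **mild** — two to four `some_difficulty`, nothing above it;
* **moderate** — five or six `some_difficulty`, or at least one
  `a_lot_of_difficulty` / `cannot_do_at_all` (severe is folded into
  moderate).

The cut-offs live in `SeverityCutoffs`. The flag
`many_some_is_moderate=False` selects the WG-recommended reporting variant,
in which five or six `some_difficulty` answers remain mild and only the
`a_lot`/`cannot` levels trigger moderate. The rule is total and exclusive
over all 4^6 = 4096 response patterns (7 none, 50 mild, 4039 moderate — the
binomial coefficients C(6,0)+C(6,1) and C(6,2..4)), and monotone: raising
any single response one step never lowers the severity.

**Affect (psychosocial proxy).** The WG Extended Set anxiety and depression
items each ask a frequency (`never … daily`) and, when frequency is not
`never`, an intensity (`a_little < in_between < a_lot`). Each construct is
scored on a four-level composite (none/mild/moderate/severe) through a
frequency x intensity grid; the respondent composite is the maximum over
the two constructs, then collapsed to two levels by merging mild into none
— the collapse aims to separate psychosocial disability from ordinary
distress. The WG's own combination grid is unpublished, so the shipped
grid is a declared stand-in: severe = daily+a_lot; moderate =
daily+in_between or weekly+a_lot; mild = daily+a_little,
weekly+a_little/in_between, monthly+a_lot; none otherwise. It is monotone
in both axes and fully overridable through configuration.

**Missingness.** Missing or refused functioning/affect responses make the
classification undefined; such records are dropped and counted, never
imputed (the survey design took no proxy interviews, so undefined records
are rare and informatively different).

## Indicator scoring

Thirty-two indicators over nine domains (4/12/2/2/2/2/3/1/4 indicators)
are each mapped to the ordered trichotomy `excluded < in_between <
included`. Fourteen indicators are binary — every substantive response is
included or excluded, and `in_between` arises only from refusals; the
remaining eighteen are nuanced, with at least one substantive `in_between`
response (e.g. mild-to-moderate food insecurity between food security and
severe insecurity).

The mapping is configuration, not code. The instrument-level cut-off
definitions behind the original study are not public, so the shipped
response maps are plausible reconstructions from the indicator names; the
choice of *which* fourteen indicators are binary is likewise a
reconstruction (indicators whose published in-between shares are near
zero, completed with the two toilet-related items). Users with a real
instrument supply their own maps via `indicator_configs_from_json`.

Refusal and item-missingness are deliberately distinct: refusals are
substantive (`in_between`), missing items drop the respondent from that
indicator's denominator. They have different statistical meaning even
though field practice often conflates them.

## Domain aggregation

A domain with *n* indicators is **included** when at least *k* indicators
are included and none of the remainder is excluded (i.e. nothing falls
below `in_between`); **excluded** symmetrically; **in between** otherwise.
The thresholds are k = 1, 1, 2, 3, 8 for n = 1, 2, 3, 4, 12 and are stored
as per-size configuration — the sequence fits no clean closed form, and
fidelity beats elegance here. The rule is total and exclusive over all 3^n
patterns (verified exhaustively up to 3^12 = 531,441), symmetric under
swapping included/excluded, and monotone. A respondent with a missing
indicator inside a domain gets a missing domain result and leaves that
domain's denominators; the source study does not describe within-domain
missingness, so this is the package's own (conservative) choice.

## Weighting

Base weights are inverse dwelling-selection probabilities from the
stratified two-stage design (province x urban/rural strata, enumeration
areas, dwellings). Raking (iterative proportional fitting) then adjusts
the weights one margin at a time to external population shares for age
group (16-24 / 25-64 / 65+), gender and population group. Defaults:
tolerance 1e-8 on margin shares, at most 100 cycles; non-convergence is
reported in the weight metadata, never silent. Raking is marginal by
design; joint-cell post-stratification is out of scope. No weight trimming
is applied by default. The raking step is written in-house (~20 lines):
no installed Python package provides survey raking, and the operational
definition is exactly the IPF update. Because the real census margins are
not part of the package, synthetic analyses rake to the scenario's own
implied margins; real analyses pass `MarginSpec` values from the relevant
census.

## Group comparisons

Each output table compares weighted category distributions across groups
(severity x gender) with a chi-squared test, Bonferroni-adjusted within
its family (9 domain tests, 32 indicator tests; the family never shrinks —
undefined members keep their slot and the family size m defaults to the
number of tests, both overridable).

Survey weights invalidate the naive Pearson test, so two design-aware
flavours are provided:

* `pearson_effective_n` (default) — rescale the weighted table to the Kish
  effective sample size (Σw)²/Σw², then classical Pearson. With unit
  weights this is *exactly* the classical test.
* `rao_scott` — first-order design-effect correction: each group's row is
  rescaled to that group's own effective size.

**Sparse cells.** Rare categories (expected counts below Cochran's rule of
5) make the asymptotic chi-squared reference anti-conservative — in null
simulations the familywise error of the nine-domain family ran well above
its nominal level through domains whose excluded category is nearly
empty. In that regime both flavours switch to a Monte-Carlo reference:
group labels are permuted over the observed (category, weight) pairs
(1000 draws), which conditions on the weight variability inside rare
cells. With few distinct weight values the permutation distribution is
sampled exactly via successive multivariate hypergeometric allocation,
which is orders of magnitude faster than label shuffling; the shuffling
path remains for many distinct weights. The Monte-Carlo seed is derived
from the table itself, so p-values are reproducible without global state.
Tables that degenerate below 2 x 2 after dropping all-zero rows/columns
report a not-available p-value, matching practice when a category is
empty for every group.

Under a null scenario (identical indicator probabilities in all groups,
n = 5000, 500 replicates) the familywise rejection rate of the nine-domain
family at alpha = 0.05 is ~0.04 — at the Bonferroni-conservative nominal
level; a 30-point single-domain inclusion shift is detected with power
~1.0.

## Reporting

* **Gaps** — male minus female percentage per unit and severity class;
  inclusion gaps at domain level (lower is worse), exclusion gaps at
  indicator level (higher is worse).
* **Severity patterns** — each indicator's gender-pooled exclusion rates
  across the three severity classes are labelled: not significant
  (adjusted p >= alpha) first; then mild and moderate within a closeness
  band (default 2 points) and both above none reads
  `mild_equals_moderate_worse`; then `monotone_worsening` (none < mild <
  moderate); residual orderings are labelled by the worst class. The band
  is checked before the monotone ordering so that near-ties such as
  (5, 22, 23) read as "mild equals moderate" rather than "monotone".
* **Prioritisation** — three targeting approaches over the pooled
  with-disability (mild+moderate, weight-pooled) domain table:
  `closest_to_inclusion` (highest inclusion below a configurable ceiling,
  default 80%, preferring large in-between mass; at-ceiling domains are
  appended last and flagged), `farthest_from_inclusion` (lowest inclusion,
  or highest exclusion by flag) and `largest_disability_gap` (largest drop
  in inclusion relative to the no-disability group). Rankings are always
  full permutations of the nine domains; ties break alphabetically and
  are flagged.

## Synthetic data

The generator emulates the structure of the survey the method was designed
for (a national multidimensional-deprivation survey of 8499 adults aged
16+), not its confidential records:

* joint disability x affect severity table calibrated to the published
  sample shares (~66.6/13.7, 6.8/2.7, 6.8/3.5 percent);
* class-conditional demographics reproducing the published skews (women
  are ~65% of the mild and ~69% of the moderate class; the 65+ share rises
  from ~5% to ~33% with severity);
* functioning and affect patterns drawn uniformly from the assigned
  class's valid pattern set, so responses classify back to the class with
  probability 1 (the published data carry no pattern-level detail; a
  configurable within-class distribution is the extension hook);
* indicator categories drawn per severity class and mapped to raw codes
  through the inverse indicator configuration, with a small refusal rate
  (default 0.5%);
* a nine-province urban/rural two-stage design with distinct sampling
  fractions (so the design is informative and raking is non-trivial).

Indicator category probabilities follow the published indicator tables'
inclusion/in-between shape, with exclusion probabilities softened so the
domain-level picture keeps its qualitative ordering (personal safety and
social relationships worst, healthcare access best): indicator responses
are drawn independently given the class, and under independence the
published indicator-level exclusion rates would contradict the published
near-zero domain-level exclusion — real deprivations co-occur, which the
independent generator cannot reproduce. A shared latent propensity hook is
the natural extension. Consequently, passing tests demonstrate that the
pipeline's *mechanics* (classification, aggregation, weighting, testing)
are correct under known generative truth; they say nothing about any real
population's inclusion levels.

## Numerical choices and problem sizes

* Category and severity codes are small integers ordered by the domain
  ordering, so monotonicity is plain integer comparison; matrices use
  nullable Int8 with NA for missing.
* Raking: tolerance 1e-8, 100 cycles, totals preserved because targets are
  shares of the running total; a positive-target level with zero sample
  weight raises an infeasibility error naming the level.
* Chi-squared: all-zero rows/columns dropped before testing; Monte-Carlo
  fallback threshold 5 expected counts; 1000 draws (p-resolution 1/1001,
  ample against thresholds of alpha/9); observed-vs-simulated comparison
  uses a 1e-12 slack so exact ties count as exceedances.
* Ties in rankings break alphabetically and are flagged rather than
  hidden.
* Tests and the acceptance script use populations of 2000-10,000
  respondents, 500 null replicates and 50-100 power replicates — sizes at
  which Monte-Carlo error is far smaller than the effects checked, while a
  full run of suite plus acceptance script completes in minutes.

## Limitations

* The indicator response maps and the binary/nuanced split are
  reconstructions; results on real data depend on supplying the true
  instrument maps.
* The affect grid is a stand-in for an unpublished scoring rule.
* The generator's independence of indicators given severity class
  understates domain-level exclusion relative to correlated real data.
* The Rao-Scott flavour is first-order only (effective-size rescaling),
  not the second-order Satterthwaite version.
* Sensitivity analysis of the k-of-n cut-offs is exposed through
  configuration but not performed here.
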