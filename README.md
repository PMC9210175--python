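# inclusion-monitor

Tools for monitoring the social inclusion of people with disabilities at
the individual level, for analysts of household-survey microdata who need
a baseline that can be disaggregated by disability severity and gender
and compared over time.

## The method

A respondent's **disability severity** is classified from the Washington
Group Short Set — six functioning questions (seeing, hearing, walking,
cognition, self-care, communication) on a four-level difficulty scale —
as *none* (≤ 1 "some difficulty"), *mild* (2–4 "some difficulty") or
*moderate* (5–6 "some difficulty", or any "a lot of difficulty" / "cannot
do at all"). **Affect severity** (a psychosocial-disability proxy) comes
from the Extended Set anxiety and depression items: a frequency ×
intensity composite per construct, maximised over constructs and
collapsed to *none*/*moderate*.

Inclusion itself is measured by 32 indicators over nine domains (social
relationships, living conditions, economic opportunities, support
systems, institutional status, voice, education, healthcare access,
personal safety). Each indicator maps to the ordered trichotomy

```
excluded < in between < included
```

and a domain of *n* indicators is *included* when at least *k* indicators
are included and none is excluded (k = 1, 1, 2, 3, 8 for n = 1, 2, 3, 4,
12) — a dual cut-off rule, applied symmetrically for exclusion, with
"in between: all else".

Design weights (inverse selection probabilities from the stratified
two-stage sample) are raked by iterative proportional fitting to
population margins for age group, gender and population group. Group
differences (severity × gender) are tested with design-aware chi-squared
tests — weighted tables rescaled to the Kish effective sample size
(Σw)²/Σw², with a permutation Monte-Carlo reference when expected cell
counts are sparse — and Bonferroni-adjusted within each family of tests
(adjusted p = min(1, m·p)).

Because the original survey's microdata are not deposited, the package
ships a calibrated synthetic-data generator (`synthetic_data`) that
reproduces the survey's structure — severity prevalences near 80/10/10%
(disability) and 80/20% (affect), the female-skewed mild/moderate
classes, the two-stage design — so every stage is testable against known
generative truth. See `docs/methods.md` for the full model description.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic population (microdata go to `scratch/`, tables to `results/`):

```
python analysis/01_simulate_survey.py
python analysis/02_run_pipeline.py
python analysis/03_gaps_patterns_priorities.py
python analysis/04_calibration_simulations.py
```

`01` draws 8499 respondents and confirms the calibration:

```
                measure  generated  scenario_target
    disability_none_pct      80.04            80.22
    disability_mild_pct       9.55             9.49
disability_moderate_pct      10.40            10.29
    affect_moderate_pct      20.05            19.88
```

`02` classifies, weights (raking converges in 3 cycles to margin error
1e-8) and tabulates. Mean inclusion per domain across the six
disability × gender groups:

```
personal_safety           17.3
social_relationships      25.9
education                 37.9
institutional_status      48.4
voice                     49.4
living_conditions         50.4
economic_opportunities    54.6
support_systems           54.7
healthcare_access         87.5
```

Personal safety and social relationships are the worst-served domains and
healthcare access the best — the qualitative shape the generator is
calibrated to. `03` then summarises gaps and priorities; the three
targeting approaches disagree, which is the point of computing all three:

```
approach    closest_to_inclusion farthest_from_inclusion largest_disability_gap
rank
1                          voice         personal_safety        support_systems
2         economic_opportunities    social_relationships              education
3           institutional_status               education      living_conditions
```

`04` checks calibration by simulation: under a null scenario the
nine-domain family rejects in 3.5% of replicates (nominal 5%); an
injected 30-point education shift is detected in 100% of replicates.

The same pipeline runs on real microdata: a CSV with the documented
column dictionary (design fields, demographics, six `wg_*` functioning
codes, four affect codes, 32 `ind_*` indicator codes), your instrument's
response maps as JSON, and `MarginSpec` raking targets from your census.
A thin CLI wraps the same calls:

```
inclusion-monitor generate --n 8499 --seed 2019 --out scratch/survey.csv
inclusion-monitor analyse --input scratch/survey.csv --out-dir results/tables
inclusion-monitor simulate --mode null --reps 200 --out results/null.json
```

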