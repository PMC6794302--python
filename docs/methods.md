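# Methods

## Data model

An admission registry is a table of hospitalizations: opaque patient id,
edition label, integer admission day, ordered ICD-9-CM diagnosis codes
(first = principal), in-hospital death flag, age. Days are offsets from
an arbitrary epoch because deidentified registries carry no calendar
dates; only intervals matter anywhere in the pipeline. Editions model
annual registry releases whose patient identifiers cannot be linked
across releases: each release holds a patient's full longitudinal
history up to its cut-off.

### Edition merging

Keeping several editions would recount surviving patients, so the merge
keeps the latest edition in full and, from earlier editions, only
patients with an in-hospital death recorded there — a deceased patient
cannot reappear in a later release. Should a patient id nevertheless
appear in several editions after merging (possible in third-party or
adversarial data), the records are collapsed by id with a warning.

### Code handling and filtering

Principal diagnoses are truncated to the three-digit chapter level
(numeric `NNN`, `Vnn`, `Ennn`), avoiding sub-classification splits
(e.g. 728.88 → 728). Admissions whose principal diagnosis is not a
disease are dropped before timeline building: obstetric codes 630–679,
injury/poisoning 800–999, external-cause E codes, administrative V
codes. The exact chapter boundaries of "non-disease" are a judgement
call; notably, perinatal-condition codes 760–779 are *retained* here.
Timelines keep, per patient, the first admission day per code, the age
at that admission, and the earliest death-flagged day; records dated
after a death are dropped with a warning (death is terminal).

## Pair association

`RA = C_ij · N / (I_i · I_j)` with `C_ij` counted over patients whose
first diagnoses of *i* and *j* lie at most `window_days` (default 365,
boundary inclusive) apart. The binomial null uses
`p0 = (I_i/N)(I_j/N)`, so the expected count is exactly `C*_ij`; the
observed count applies the one-year window while the expectation does
not. This asymmetry is deliberate and inherited from the method being
reproduced: the window can only shrink `C_ij`, so for diseases whose
diagnoses fall far apart the test loses power but never gains false
positives. In particular, under complete independence with admission
days uniform over a 20-year span, windowed RA concentrates near
2·365/7300 ≈ 0.1, far below 1 — the null is strongly conservative. The
test is one-sided (upper tail) because only "more co-occurrence than
chance" is ever selected. BH adjustment runs over all pairs with both
incidences positive, as one family; zero-incidence pairs are never
tested. One significance family per criterion: the association screen
and the direction screen are adjusted separately, each at FDR < 0.1.

## Temporal direction

Order indicators use strict day comparison; same-day pairs are excluded
(the standard sign-test treatment of ties — the indicator is defined
only as ±1). The sign test is the exact two-sided binomial against 1/2
(doubled smaller tail, capped at 1), since the selection criterion is
δ ≠ 0. Both the association window ("within one year") and the
direction window ("less than one year" in the source description) are
implemented as ≤ 365 days; the one-day discrepancy at the boundary is
noted and immaterial at registry scale. Interval statistics (mean, n−1
SD) are computed over forward-ordered patients only.

## Trajectory DAGs

Directed pairs are sorted by patient count, descending, with
deterministic lexical tie-breaks. Every distinct source disease roots a
candidate trajectory; from a path's terminal, *all* viable extensions
are attached (real progression graphs branch), where viable means at
least one patient follows the entire extended sequence — strictly
increasing first-diagnosis days, each consecutive gap ≤ window. Each
path is tracked separately for follower counting; a path terminates
when no extension has a follower. Followers dying in hospital on or
after the final diagnosis feed a terminal death node; death is optional
— paths whose followers all survive are kept. No cap is placed on path
length (the data decide). Node and edge annotations are unions of
prefix-follower sets, which guarantees edge count ≤ min(endpoint
counts); a patient traversing several branches is counted once per
node, and per-path follower counts are reported separately because
"once per path" vs "once per DAG" is genuinely ambiguous — both are
available in the outputs. Acyclicity is verified on every built graph;
supplying both orientations of a pair raises immediately.

## Cohort statistics

Relative risk uses the Wald log-RR construction
(`exp(ln RR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))`) with a two-sided
normal p-value on ln RR, the standard choice where the original method
is unstated; an optional 0.5 continuity correction handles zero cells.
Hypergeometric enrichment is the upper tail P(X ≥ k). These reproduce
in-text arithmetic on explicit counts; published p-values whose exact
population/sample parameterizations are unrecoverable are not targeted.

## Synthetic registry

The generator emulates the structure of restricted statewide inpatient
data: multi-edition releases (optionally with deceased-only backfill,
i.e. earlier editions contribute only patients absent from the latest
and flagged deceased), ~20-year windows, three-digit disease codes
occasionally emitted at sub-code resolution to exercise truncation, a
configurable fraction of non-disease admissions, per-code death hazards
applied to a patient's last admission, and ages drawn around
63.8 ± 19.6 years at entry.

Disease sets are marginal Bernoulli draws, pair-coupled per planted
ordered pair (i, j, lift): patients with *i* have their *j* status
redrawn at min(1, lift·rate_j), patients without *i* at the compensated
rate rate_j(1 − lift·rate_i)/(1 − rate_i), so P(both) = lift·rate_i·
rate_j while the marginal of *j* stays exactly rate_j. The compensation
is this package's design choice: without it the target marginal
inflates and E[RA] falls to lift/(1 + (lift−1)·rate_i), an avoidable
bias. Planted inter-diagnosis gaps are truncated normal (≥ 1 day;
default 114.9 ± 84.3 days, the scale reported for real comorbidity
pairs), forward with probability `direction_prob`; when planted pairs
chain (i→j, j→k) a later pair anchors on an already-coupled source day
so multi-step trajectories compose. Unrelated admission days are
uniform over the study window.

Two systematic features of the stated world matter when reading
estimates:

- **Registry coverage.** A simulated patient with no admission does not
  exist in the registry, so the patient total the estimator sees is
  n_patients × f with f = P(≥ 1 admission); E[RA] carries the factor f.
  The standard worlds use 30–50 diseases at rates 0.03–0.15, giving
  f ≥ 0.95.
- **Truncation shift.** Truncating N(114.9, 84.3²) at 1 day moves the
  realized forward-gap mean to ≈ 130 days and shrinks its SD to ≈ 68;
  the generator reports the distribution it actually samples.

What the generator does **not** emulate: hospital-level clustering,
seasonal admission patterns, coding drift over calendar time, secondary
diagnoses influencing outcomes, within-patient clustering of unrelated
admissions (real admissions cluster in time; simulated unrelated days
are uniform, which makes windowed null RA ≈ 0.1 rather than ≈ 1). A
green recovery test therefore establishes correctness of the estimator
under conditional independence plus planted pairwise coupling — not
realism of any particular clinical association.

## Numerical and determinism notes

- All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical config + seed gives byte-identical
  registries and output tables.
- Binomial/hypergeometric tails use scipy survival functions (stable
  log-space tail sums); both are oracle-tested against exact
  enumeration at small n to 1e-12.
- BH q-values follow the step-up definition with a reverse cumulative
  minimum; ties in p are handled by stable sorting.
- Greedy construction breaks patient-count ties lexically on
  (source, target), so trajectory output is deterministic.

## Known limitations

- The windowed-count / unwindowed-expectation asymmetry of RA makes the
  association screen conservative for pairs with long inter-diagnosis
  intervals; alternatives (windowed expectation) were not explored in
  the original method and are out of scope.
- Death hazards attach only to a patient's final admission, so
  simulated mortality is lower than per-admission hazards would give.
- Published counts of significant pairs on restricted data are
  internally inconsistent in the source material (682 vs 300) and are
  not reproduction targets; the pipeline's thresholds (RA > 1,
  FDR < 0.1 at both stages) are what is reproduced.
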