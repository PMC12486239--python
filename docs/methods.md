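# Methods

## Model and scope

`msbalance` implements minimal sufficient balance (MSB) allocation for
a 2-arm sequential trial. The unit of randomization is an individual or
a two-member dyad allocated together; each unit carries one covariate
vector (how dyad members' covariates are combined into that vector is
the caller's decision — the engine is deliberately agnostic to the
combination rule). The first listed arm is "arm 0" everywhere, and a
positive standardized or risk difference means arm 0's mean or
proportion is larger; this fixed sign convention makes exported balance
tables reproducible.

MSB's premise is that adaptive intervention should be *minimal*: the
coin is biased only when a pre-specified imbalance criterion is
statistically triggered, so most allocations remain plain fair-coin
draws and allocation randomness (and hence predictability resistance)
is largely preserved.

## Engine parameters

| parameter | default | meaning |
|---|---|---|
| `p_threshold` (η) | 0.3 | per-covariate test significance below which a vote is cast; deliberately liberal, since the test is a trigger, not an inference |
| `biased_probability` (p_b) | 0.7 | biased-coin probability for the favored arm; any value in (0.5, 1) |
| `burn_in` (m) | 20 units | initial simple 1:1 allocations; imbalance tests are uninformative at tiny n |
| `size_balance` | on | whether arm-size imbalance (exact binomial test at rate ½) votes, under the criterion name `sample_size`, on equal footing with covariates |
| `seed` | 0 | seed of the single shared allocation stream, consumed one uniform per allocation in enrollment order |

None of these defaults is an estimate recovered from any particular
trial; they are conventional MSB/biased-coin choices and are all
configurable in the run configuration.

## Imbalance tests and votes

Continuous covariates use Welch's (unequal-variance) two-sample
*t*-test — the robust default when nothing is known about arm
variances. Binary and categorical covariates use the chi-square test of
two proportions without continuity correction, switching to Fisher's
exact test whenever any expected cell count falls below 5 (the
correction-free statistic keeps the large-sample path exactly the
textbook proportions test; the Fisher fallback covers the small-sample
regime deterministically). Categorical covariates are tested
one-vs-rest at the incoming unit's own level: the engine needs a
direction for its vote, which an omnibus test cannot give. No
multiplicity adjustment is applied across covariates — votes are
per-covariate by design.

Vote direction, given a triggered test and a non-missing value on the
incoming unit:

* binary/categorical — a unit carrying the indicator trait votes for
  the arm where the trait is currently rarer, a unit without it for the
  arm where the trait is more common; equal proportions cast no vote.
* continuous — the vote goes to the arm whose hypothetical
  post-assignment |d| is smaller, evaluated exactly in O(1) from the
  running per-arm moments. For values clearly outside the two arm means
  this coincides with the classical shortcut (send values above the
  pooled mean to the low-mean arm); the exact evaluation was chosen
  because the shortcut provably picks the wrong arm when the value
  falls between the pooled mean and the farther arm mean, which breaks
  the guarantee — relied on by the property suite — that a vote never
  increases the covariate's |d| relative to the alternative arm. A
  value exactly at the pooled mean, equal arm means, or equal
  hypothetical |d| casts no vote.

A strict majority of votes (covariates plus, when enabled, the
`sample_size` criterion) earns that arm probability p_b; ties and empty
tallies yield a fair coin. The recorded `criteria` list names the
criteria that voted for the favored arm, and is empty exactly when no
bias was applied.

Missing covariate values are permitted when the spec is not `required`:
the unit is simply excluded from that covariate's test denominator and
casts no vote for it. A covariate can be activated mid-trial via
`active_from` (an enrollment index, not a calendar date — simulation
and replay then need no clock); before that index it neither tests nor
votes.

## Numerical choices

* Per-arm sufficient statistics (counts per level; n, Σx, Σx² for
  continuous) are maintained incrementally by the trial state, so each
  per-allocation test costs O(1) and a 2,086-unit trial simulates in
  about a second. P-values come from the closed-form statistics through
  `scipy.stats` distribution functions; the test suite verifies
  agreement with `scipy.stats.ttest_ind`, `chi2_contingency`,
  `fisher_exact` and `binomtest` to 10⁻⁸ over a thousand random
  instances.
* Degenerate data (an arm with no non-missing values, or fewer than 2
  for a continuous test) yields a report with p = 1 and no statistic,
  which can never vote. A zero pooled spread with unequal means returns
  a signed-infinity standardized difference as an explicit sentinel.
* The two-sided exact binomial p-value at rate ½ is computed as twice
  the smaller tail, capped at 1 — identical to the minimum-likelihood
  convention in the symmetric case.

## Workflow semantics

`handle_trigger` composes readiness checking (right project, right
instrument name matched case-insensitively, unit exists, randomization
indicator set, arm unset), covariate validation, the MSB draw, the
store write-back and the audit append, and always produces exactly one
JSON-lines audit entry per trigger. The store write precedes the
in-memory commit, so any write failure leaves the unit unrandomized
everywhere and is logged as `failed_error`; trigger re-delivery after
success is idempotent (`ignored_already_randomized`). A crash between
the store write and the log append is surfaced later by the `check`
consistency scan (unit with an arm but no successful audit entry) —
the design goal is reconcilable logs, not transactional storage.

The record store is CSV (UTF-8, header row, RFC-4180 quoting,
`covariate.<name>` columns, empty cell = missing) or an equivalent
JSON form; the two are losslessly interconvertible. Writes are atomic
(temp file + rename) with optimistic concurrency: a snapshot carries a
content hash, a write against a stale snapshot fails without touching
the file, and a version counter in a sidecar `<store>.meta.json`
increments by exactly 1 per successful write. Optimistic versioning was
preferred over file locks as a portable, testable contract.

Backup allocations (outage contingency) consume a pre-generated fair
1:1 list strictly in order; an applied entry is recorded with
`source = backup_list` at probability 0.5 and from then on is
indistinguishable, for every balance computation, from an algorithmic
allocation — that is the whole reconciliation contract. The CLI
recovers the list pointer as the count of backup-sourced units in the
store.

### Run configuration schema

```json
{
 "arms": ["intervention", "control"],
 "covariates": [
  {"name": "age", "kind": "continuous", "active_from": 0, "required": true},
  {"name": "prep_use", "kind": "binary", "levels": ["no", "yes"]},
  {"name": "status", "kind": "categorical", "levels": ["single", "partnered_alone", "dyad"]}
 ],
 "msb": {"p_threshold": 0.3, "biased_probability": 0.7, "burn_in": 20,
         "size_balance": true, "seed": 2022}
}
```

Omitted `msb` fields take the defaults above. Binary specs must have
exactly 2 levels, categorical at least 2, continuous none.

## Synthetic population

The shipped default emulates the covariate roster of an HIV-prevention
trial in 16–34-year-olds that balanced on seven covariates, including a
baseline STI covariate added to the algorithm mid-enrollment
(modelled here as `active_from = 1000`):

| covariate | kind | marginal |
|---|---|---|
| status | 3-level | 0.55 / 0.15 / 0.30 |
| limited_participation | binary | prevalence 0.15 |
| race_ethnicity | 4-level | 0.45 / 0.20 / 0.20 / 0.15 |
| gnc_trans | binary | prevalence 0.20 |
| prep_use | binary | prevalence 0.35 |
| sti | binary | prevalence 0.10, active from unit 1000 |
| age | continuous | uniform on [16, 34] |

Units are dyads with probability 0.3. These marginals are mid-range
plausible values chosen once for the simulator — they are **not**
estimates of any trial population, and covariates are drawn
independently of one another and of dyad status (no correlation
structure; the configuration object is the natural extension point if
one is needed). Consequently the simulation demonstrates properties of
the *allocation algorithm* — balance under a realistic covariate mix —
not properties of any real cohort: real enrollment streams have
correlated covariates, temporal drift, and data-entry errors that this
generator does not emulate, so passing simulation thresholds here says
nothing about operational data quality.

## Problem sizes

The scheme comparison replicates 2,086-unit trials (the enrollment
scale the pipeline is aimed at) 100 times per scheme, with a fresh
enrollment stream per replicate shared across schemes for pairing; it
reports the mean and 95th percentile of the end-of-trial maximum |d|
across covariates (and maximum risk difference across non-continuous
covariates), plus the fraction of replicates exceeding the conventional
validity thresholds d = 0.1 and 10%. For categorical covariates the
summary takes the worst one-vs-rest level, making it conservative.

## Known limitations

* Two arms only, equal target allocation; no stratification or
  minimization schemes, and no response-adaptive features.
* No outcome or power simulation — the endpoint side of a trial is out
  of scope.
* The trigger dialect (`project_id`, `record`, `instrument` keys) and
  the form-name match are declared conventions, configurable but not
  recovered from any production system; there is no live EDC/API
  integration, authentication, or blinding enforcement.
* The store is a single flat file with optimistic versioning — adequate
  for one coordinating process and auditable replay, not a multi-writer
  database.
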