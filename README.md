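# msbalance

Covariate-adaptive randomization for 2-arm sequential trials with the
**minimal sufficient balance (MSB)** algorithm, plus the surrounding
automation a trial actually needs: a trigger-driven workflow that
randomizes a participant the moment their "Randomization" form is saved,
a file-backed record store with audit logging, a static backup list for
outages, and a Monte-Carlo simulator that quantifies how much covariate
balance MSB buys over simple randomization.

It is written for trial biostatisticians and data managers who want a
desk-scale, fully scriptable MSB pipeline: every step is a plain Python
call or a `msb` CLI command operating on CSV/JSON files, so the whole
allocation sequence is reproducible and auditable offline.

## The algorithm

Simple randomization can leave study arms accidentally imbalanced on
prognostic covariates. MSB intervenes only when imbalance is
demonstrable, preserving allocation randomness the rest of the time.
For each incoming unit of randomization (an individual or a partnered
dyad allocated together), with arms indexed 0 and 1:

1. **Test** each active balancing covariate on the already-randomized
   units: Welch's two-sample *t*-test for continuous covariates; a
   chi-square test of proportions (Fisher's exact when any expected cell
   is below 5) for binary/categorical covariates, taken one-vs-rest at
   the incoming unit's own level. Imbalance is summarized by the
   standardized difference

   *d* = (x̄₀ − x̄₁) / s_pooled   (continuous),  
   *d* = (p̂₀ − p̂₁) / √[(p̂₀(1−p̂₀) + p̂₁(1−p̂₁))/2]   (proportions),

   and, for non-continuous covariates, the risk difference p̂₀ − p̂₁.
2. **Vote**: a covariate whose test has *p* < η (default η = 0.3) casts
   a vote for the arm the incoming unit should join to shrink its
   imbalance — a trait-positive unit goes where the trait is rarer; a
   continuous value goes to the arm whose post-assignment |*d*| would be
   smaller. An optional arm-size criterion (exact binomial test of the
   current split against 1:1) votes for the smaller arm.
3. **Allocate**: a strict majority of votes earns that arm the biased
   coin *p_b* = 0.7 (> 0.5); ties or no votes fall back to a fair coin.
   The first 20 units (burn-in) are always allocated 1:1.

Each allocation records the arm, the probability used, the vote tally,
the triggering criteria, and the uniform draw consumed — enough to
replay and audit the entire sequence from the seed.

## Worked example

Given a run configuration (`config.json`, arms + covariate specs +
engine parameters) and a record store (`store.csv`) holding 60
randomized units in which PrEP use has drifted to 21/31 vs 13/30
between arms, saving the Randomization form for the ready unit `P060`
(a PrEP user) fires a trigger that the CLI processes directly:

```sh
msb randomize --config config.json --store store.csv --log audit.jsonl \
    --project 1207 --trigger "project_id=1207&record=P060&instrument=Randomization"
```

```json
{
 "record_id": "P060",
 "outcome": "randomized",
 "detail": "unit 'P060' -> 'intervention'",
 "allocation": {
  "unit_id": "P060",
  "arm": "intervention",
  "probability_used": 0.7,
  "arm_probability": 0.30000000000000004,
  "favored_arm": "control",
  "votes_arm0": 0,
  "votes_arm1": 2,
  "criteria": ["age", "prep_use"],
  "rng_draw": 0.04509843138835257,
  "source": "algorithm"
 }
}
```

Two balance criteria triggered (age and PrEP use, both currently higher
in the intervention arm), so the engine favored **control** with
probability 0.7 — and the recorded draw 0.045 then landed on the 30%
side, a reminder that MSB biases the coin rather than forcing the arm.
The allocation is written back to `store.csv` and appended to
`audit.jsonl`; replaying the same trigger is a no-op
(`ignored_already_randomized`). `msb report` exports the Table-1-style
balance table, `msb gen-backup` / `msb apply-backup` manage the outage
contingency list, and `msb check` scans for store/log divergence.

## Simulation

```sh
msb simulate --n-units 2086 --n-reps 100 --seed 1 --out-dir sim/
```

replicates full trials of 2,086 units under MSB and under simple
randomization using the shipped 7-covariate population (participation
status, limited participation, race/ethnicity, GNC/trans identity,
PrEP use, a mid-trial-activated STI covariate, and age uniform on
16–34), and summarizes the end-of-trial worst-case |*d*| and risk
difference per scheme against the conventional validity thresholds
*d* = 0.1 and 10%.

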