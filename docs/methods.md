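# Methods

## Model

A cohort of patients with advanced biliary tract cancer is tracked through
three health states — progression-free on chemotherapy (*no progress*),
progressed to palliative care (*progress*), and *death* — in monthly cycles
over a 36-month horizon, separately for the two strategies: gemcitabine plus
cisplatin (GC) and gemcitabine alone (G).

Monthly transition probabilities are derived from trial medians under the
constant-hazard assumption: *p* = 1 − e^(−r), with r = ln 2 / median. The
overall-survival medians (11.2 / 7.7 months) give the monthly mortality
probabilities 0.0600 / 0.0861, and the progression-free-survival medians
(5.8 / 3.7 months) give the monthly progression probabilities
0.1126 / 0.1708. Because the same death probability applies from both alive
states, the modeled survival curve is exactly geometric,
S(k) = (1 − p_death)^k, so the model reproduces the trial medians
(continuous interpolation ln 0.5 / ln(1 − p)) and the implied hazard ratio
ln(1 − p_GC) / ln(1 − p_G) = 0.687 by construction. This is the model's
calibration check (`cea validate`).

### Transition structure

How progression and death combine within a cycle is a genuine modelling
choice; two structures are implemented, both leaving survival geometric:

* **competing** (default): from *no progress*, the cohort moves to
  *progress* with p_progress and to *death* with p_death, staying with
  1 − p_progress − p_death;
* **conditional**: progression applies to the month's survivors,
  NP→P = (1 − p_death) · p_progress.

The competing structure is the default because it reproduces the published
base-case cost and QALM totals for both arms within ±4.5 %, whereas the
conditional structure leaves the monotherapy arm's cost about 6.7 % short.
The switch is `analysis.progression_conditional` in the config. In the
competing structure p_progress + p_death must not exceed 1 (amply satisfied
here; the engine raises otherwise).

### Rewards and discounting

Per cycle spent in *no progress*: outpatient + inpatient + drug cost, plus
the expected cost of treating adverse events (the arm's AE probability times
the monthly G-CSF cost); utility is the AE-probability-weighted mixture of
the AE utility (0.678) and the progression-free utility (0.690). Per cycle
in *progress*: the palliative-care cost (49,260 + 780 meal yen/day × 30 days
= 1,501,200 yen/month) at utility 0.710. Death accrues nothing. Whether
inpatient and outpatient costs should continue past progression is unstated
in the source; here they stop at progression and palliative care takes over.

Rewards accrue at cycle start, cycles 0..35, discounted by (1 + d)^(−k)
with d = 1.03^(1/12) − 1 ≈ 0.0024663 (compound annual-to-monthly
conversion; the simple division d = 0.03/12 differs only in the fifth
significant digit). A half-cycle correction (trapezoid weights ½ on the
first and last cycle, with the trace extended one cycle) is available via
`analysis.half_cycle` but off by default; at these survival times it changes
totals by ~3 % and no verdict.

## Outcomes

ΔQALY = ΔQALM / 12 exactly; ICER = ΔCost / ΔQALY. The verdict at the
willingness-to-pay threshold (6,000,000 yen/QALY) is always decided by the
sign of the incremental net monetary benefit NMB = WTP · ΔQALY − ΔCost,
which coincides with ICER < WTP whenever ΔQALY > 0 and extends cleanly to
the dominance quadrants that probabilistic draws can produce (dominant:
cheaper and more effective; dominated: costlier and less effective;
tradeoff: cheaper and less effective, cost-effective when the savings per
QALY forgone exceed the threshold).

The published base-case table is internally inconsistent: its effect totals
(10.04 − 7.61) imply an increment of 2.43 QALM, but the printed increment
and the printed ICER use 2.73 QALM. The package reports its own consistent
increments and reproduces each printed total within a few percent; exact
reproduction of every printed cell is impossible by construction.

## Parameter uncertainty

Each uncertain parameter carries a distribution:

* **beta** for probabilities (transition and adverse-event rows). Default
  parameterization is count-based, Beta(r, n − r) with r = mean · n from the
  published mean and sample size — the construction whose mean r/n and
  SD √(r(n−r)/(n²(n+1))) the source states. Moment matching to a printed
  (mean, SD) is available per entry (`beta_by: moments`); it is not the
  default because the printed SD column is internally inconsistent (the
  GC-mortality SD 0.0162 corresponds to no plausible n, and the
  adverse-event SDs match arm-level rather than pooled sample sizes).
* **gamma** for utilities and the two surveyed monthly costs, with
  shape = (mean/sd)² and scale = sd²/mean. Sampled utilities are clamped at
  1.0 (`analysis.clamp_utilities`), since a gamma has unbounded support and
  weights above perfect health are not meaningful.
* **triangular** for tariff-based drug and care costs, on the published
  (minimum, mode, maximum). The ±10 % rule reproduces the published bounds
  exactly for the G-CSF and both drug-cost rows; the palliative bounds
  (1,330,020 / 1,625,580) are *not* ±10 % of the mode and ship verbatim.

The PSA draws every distributed parameter jointly and independently
(n = 10,000 by default), re-runs the full deterministic pipeline per draw,
and reports the CEAC: the fraction of draws with positive incremental NMB at
each WTP on a grid (0–20 million yen in 250,000-yen steps by default).
Discount rate and horizon stay fixed in the PSA. Reproducibility: one root
seed is split into per-parameter substreams (`SeedSequence.spawn`, sorted
parameter order), so results are bit-identical across runs at the same
library versions and a parameter list edit does not reshuffle unrelated
draws. At the threshold the acceptability is ≈ 0.41 under the count-based
betas (seed-to-seed spread well under ±0.01); the published figure is "about
a third" in one place and "about 40 %" in another, a spread the
parameterization ambiguity above comfortably spans.

## Deterministic sensitivity analysis

Twelve published one-way ranges (labels A–M, no I) ship in
`data/dsa_ranges.yaml`, including two known quirks preserved as data: range
B's low end was printed as "5" and ships as 0.05; range D duplicates C's
numbers as printed. Range G sweeps the monthly discount directly
(8.0×10⁻⁴–0.0043). Each range re-runs the full pipeline at both bounds.
Entries are sorted by ICER span; the combination-arm mortality probability
(range A) has by far the widest span. At extreme bounds of the mortality and
progression ranges (A high, B low, C low) the combination becomes
cost-saving — it dominates or saves more per QALY forgone than the
threshold — so the one-way verdict does flip there; the tornado output
flags this per entry (`flips_verdict`) rather than asserting the base case
is unconditionally robust.

## Synthetic data and oracles

`simulate_patients` is an individual-level microsimulation of the identical
chain with the identical accrual convention (shared reward code path), so a
disagreement with the cohort engine isolates trace errors rather than
convention drift; agreement is asserted within 3 standard errors at 20,000
patients per arm. `generate_trial` draws per-patient exponential times to
progression and death at hazards ln 2 / median, censored at the horizon —
emulating the trial summary statistics, not its patient-level data:
real trials have non-exponential hazards, dependent censoring and
within-patient correlation that the generator deliberately omits, so these
tests validate the derivation arithmetic, not the clinical realism of the
constant-hazard assumption. `recover_probabilities` estimates hazards by
events / person-time — the censored-exponential maximum-likelihood
estimator, using exact event times rather than whole months, which keeps the
estimate unbiased (month-rounding would bias hazards upward by the mean
residual within-month time, ~4–9 % here) — and converts them back through
p = 1 − e^(−r); the round trip recovers all four transition probabilities
within 2 % at n = 100,000.

## Numerical conventions and limitations

* Currency is full-precision float internally; reports round half away from
  zero to the whole yen.
* Problem sizes in the test suite: 10,000 PSA draws (the published count),
  20,000 microsimulation patients per arm, 100,000 trial patients for
  parameter recovery.
* The model has no tunnel states, no time-varying hazards, no second-line
  therapy, no parameter correlation in the PSA, and no cost heterogeneity
  beyond state membership. Utilities come from a foreign registry (no
  Japan-specific values existed); costs rest on a small single-centre
  receipt survey. Conclusions are specific to the Japanese payer
  perspective and the 2012 fee schedule.
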