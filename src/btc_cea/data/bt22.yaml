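# Model inputs for gemcitabine+cisplatin (gc) vs gemcitabine alone (g) in
# advanced biliary tract cancer, Japanese payer perspective, monthly cycles.
#
# Transition probabilities are monthly values derived from the trial medians
# via p = 1 - exp(-ln2/median): overall survival 11.2 (gc) / 7.7 (g) months,
# progression-free survival 5.8 (gc) / 3.7 (g) months. Costs are yen/month
# (2012 national fee schedule and a hospital receipt survey); the palliative
# monthly cost is (49,260 + 780 meal) yen/day x 30 days = 1,501,200.
arms:
  gc:
    p_progress: 0.1126
    p_death: 0.0600
    p_ae: 0.707
    cost_drug: 44574
  g:
    p_progress: 0.1708
    p_death: 0.0861
    p_ae: 0.688
    cost_drug: 43947
costs:
  outpatient: 35148
  inpatient: 212990
  palliative: 1501200
  gcsf: 27613
utilities:
  no_progress: 0.690
  progress: 0.710
  adverse_event: 0.678
analysis:
  horizon_months: 36
  discount_annual: 0.03
  wtp_per_qaly: 6000000
  half_cycle: false
  progression_conditional: false
  clamp_utilities: true

# Uncertainty distributions for the probabilistic analysis. Betas are built
# from counts, Beta(r, n-r) with r = mean*n (beta_by: counts); the printed
# sd column is retained for the moment-matching variant (beta_by: moments).
# Note the gc.p_death printed sd (0.0162) is inconsistent with its n; the
# count-based build sidesteps that. Triangular cost bounds are the published
# values; the palliative bounds are NOT +/-10% of the mode and are shipped
# verbatim.
distributions:
  - {param: gc.p_ae, kind: beta, mean: 0.707, sd: 0.071, n: 206}
  - {param: g.p_ae, kind: beta, mean: 0.688, sd: 0.07, n: 206}
  - {param: gc.p_progress, kind: beta, mean: 0.1126, sd: 0.0494, n: 41}
  - {param: g.p_progress, kind: beta, mean: 0.1708, sd: 0.0581, n: 42}
  - {param: gc.p_death, kind: beta, mean: 0.0600, sd: 0.0162, n: 41}
  - {param: g.p_death, kind: beta, mean: 0.0861, sd: 0.0433, n: 42}
  - {param: utilities.no_progress, kind: gamma, mean: 0.690, sd: 0.120}
  - {param: utilities.progress, kind: gamma, mean: 0.710, sd: 0.130}
  - {param: utilities.adverse_event, kind: gamma, mean: 0.678, sd: 0.120}
  - {param: costs.outpatient, kind: gamma, mean: 35148, sd: 22402}
  - {param: costs.inpatient, kind: gamma, mean: 212990, sd: 104633}
  - {param: costs.palliative, kind: triangular, minimum: 1330020, mode: 1501200, maximum: 1625580}
  - {param: costs.gcsf, kind: triangular, minimum: 24852, mode: 27613, maximum: 30374}
  - {param: g.cost_drug, kind: triangular, minimum: 39552, mode: 43947, maximum: 48342}
  - {param: gc.cost_drug, kind: triangular, minimum: 40117, mode: 44574, maximum: 49031}
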