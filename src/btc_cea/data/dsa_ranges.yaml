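# One-way sensitivity ranges for the tornado diagram (published ranges A-M;
# there is no entry I in the source labelling).
#
# Known quirks, shipped as data so users can correct them:
#   - B was published as "(5-0.129)", an evident typo; shipped as 0.05-0.129.
#   - D was published with the same numbers as C; shipped as printed.
#   - E ("utility of progression-free survival") and J ("utility of
#     pre-progress") both plausibly describe the pre-progression state; they
#     are mapped E -> utilities.progress and J -> utilities.no_progress so
#     each utility is swept exactly once.
#   - G sweeps the monthly discount directly (analysis.discount_monthly
#     overrides the compound-converted annual rate).
- {label: A, param: gc.p_death, low: 0.0, high: 0.083}
- {label: B, param: g.p_death, low: 0.05, high: 0.129}
- {label: C, param: gc.p_progress, low: 0.045, high: 0.119}
- {label: D, param: g.p_progress, low: 0.045, high: 0.119}
- {label: E, param: utilities.progress, low: 0.445, high: 0.965}
- {label: F, param: utilities.adverse_event, low: 0.443, high: 0.913}
- {label: G, param: analysis.discount_monthly, low: 0.0008, high: 0.0043}
- {label: H, param: costs.palliative, low: 1330020, high: 1625580}
- {label: J, param: utilities.no_progress, low: 0.445, high: 0.925}
- {label: K, param: costs.inpatient, low: 191691, high: 234289}
- {label: L, param: gc.p_ae, low: 0.55, high: 0.826}
- {label: M, param: g.p_ae, low: 0.58, high: 0.846}
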