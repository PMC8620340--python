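# Default per-parameter objectives, standards (S) and ideals (V0).
#
# These are guideline-derived assumptions for an Indian river monitoring
# context (CPCB designated-best-use bathing class and BIS drinking-water
# limits), shipped so the pipeline runs out of the box.  They are NOT the
# (unpublished) values of any particular study; override with your own file
# for a real assessment.  V0 = 7.0 for pH and 14.6 mg/L for DO follow the
# classical weighted-index convention; V0 = 0 elsewhere.
objectives:
  - parameter: temperature
    direction: upper_limit
    objective_high: 30.0      # deg C, assumed comfort bound
    standard_S: 30.0
    ideal_V0: 0.0
    include_in_ccme: false
    include_in_bc: false
    include_in_weighted: true
  - parameter: pH
    direction: range
    objective_low: 6.5
    objective_high: 8.5
    standard_S: 8.5
    ideal_V0: 7.0
    include_in_ccme: true
    include_in_bc: true
    include_in_weighted: true
  - parameter: EC
    direction: upper_limit
    objective_high: 2250.0    # umhos/cm, irrigation guideline
    standard_S: 2250.0
    ideal_V0: 0.0
    include_in_ccme: false
    include_in_bc: true
    include_in_weighted: true
  - parameter: DO
    direction: lower_limit
    objective_low: 5.0        # mg/L, bathing class minimum
    standard_S: 5.0
    ideal_V0: 14.6
    include_in_ccme: true
    include_in_bc: true
    include_in_weighted: true
  - parameter: BOD
    direction: upper_limit
    objective_high: 3.0       # mg/L, bathing class maximum
    standard_S: 3.0
    ideal_V0: 0.0
    include_in_ccme: true
    include_in_bc: true
    include_in_weighted: true
  - parameter: nitrate_nitrite
    direction: upper_limit
    objective_high: 45.0      # mg/L, drinking-water nitrate limit
    standard_S: 45.0
    ideal_V0: 0.0
    include_in_ccme: false
    include_in_bc: true
    include_in_weighted: true
  - parameter: FC
    direction: upper_limit
    objective_high: 2500.0    # MPN/100 mL, bathing class maximum
    standard_S: 2500.0
    ideal_V0: 0.0
    include_in_ccme: true
    include_in_bc: true
    include_in_weighted: true
  - parameter: TC
    direction: upper_limit
    objective_high: 5000.0    # MPN/100 mL, bathing class maximum
    standard_S: 5000.0
    ideal_V0: 0.0
    include_in_ccme: false
    include_in_bc: true
    include_in_weighted: true
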