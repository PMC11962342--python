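# SYNTHETIC illustrative EQ-5D-5L tariff.
#
# These decrements are NOT a published national value set; they are a
# stand-in with the structural properties a real tariff has (zero
# decrement at level 1, decrements non-decreasing in level, worst state
# valued below 0).  Supply your country's value set for real analyses.
full_health_value: 1.0
dimensions:
  - mobility
  - self_care
  - usual_activities
  - pain_discomfort
  - anxiety_depression
decrements:
  mobility:            [0.0, 0.04, 0.07, 0.13, 0.21]
  self_care:           [0.0, 0.05, 0.08, 0.16, 0.21]
  usual_activities:    [0.0, 0.04, 0.06, 0.12, 0.16]
  pain_discomfort:     [0.0, 0.06, 0.08, 0.20, 0.28]
  anxiety_depression:  [0.0, 0.07, 0.11, 0.26, 0.33]
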