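# Default instrument definition.
#
# Ordinal response levels are 0 = absent, 1 = mild, 2 = moderate,
# 3 = severe with unit weights; these stand in for the deployed
# instrument's proprietary weights and are fully overridable.
# The EDSS item has 21 half-point levels (level l encodes EDSS = l/2)
# and contributes the raw EDSS value to disease activity when the
# with-EDSS variant is active.
name: ms-progression-default
include_edss: true
score_max: 100
normalize_sections: false
cutoffs:
  lower: 51.6
  upper: 58.9
sections:
  - name: disease_activity
    items:
      - id: relapses
        weights: [0, 1, 2, 3]
      - id: edss
        weights: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0,
                  5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0]
  - name: symptoms
    items:
      - id: fatigue
        weights: [0, 1, 2, 3]
      - id: ambulatory
        weights: [0, 1, 2, 3]
      - id: motor
        weights: [0, 1, 2, 3]
      - id: sensory
        weights: [0, 1, 2, 3]
      - id: coordination_balance
        weights: [0, 1, 2, 3]
      - id: cognitive
        weights: [0, 1, 2, 3]
      - id: bowel_bladder
        weights: [0, 1, 2, 3]
  - name: impacts
    items:
      - id: self_care
        weights: [0, 1, 2, 3]
      - id: mobility
        weights: [0, 1, 2, 3]
      - id: hobbies_leisure
        weights: [0, 1, 2, 3]
      - id: work
        weights: [0, 1, 2, 3]
      - id: daily_activities
        weights: [0, 1, 2, 3]
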