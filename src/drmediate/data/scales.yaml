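# Instrument registry: item structure, total-score ranges and case cut-offs.
scales:
  sdq_hyperactivity:
    label: "SDQ hyperactivity/inattention subscale (exposure, age 12)"
    item_count: 5
    item_levels: [0, 1, 2]
    total_range: [0, 10]
    transform: identity
    direction: higher-worse
  gaming:
    label: "Problematic online gaming symptom count (mediator, age 14)"
    item_count: 9
    item_levels: [0, 1]
    total_range: [0, 9]
    transform: identity
    direction: higher-worse
  smfq:
    label: "Short Mood and Feelings Questionnaire (depressive symptoms)"
    item_count: 13
    item_levels: [0, 1, 2]
    total_range: [0, 26]
    transform: identity
    direction: higher-worse
  cbcl_anxiety:
    label: "CBCL anxiety subset (14 items)"
    item_count: 14
    item_levels: [0, 1, 2]
    total_range: [0, 28]
    transform: identity
    direction: higher-worse
  apss:
    label: "Adolescent Psychotic-like Symptom Screener"
    item_count: 7
    item_levels: [0, 0.5, 1]
    total_range: [0, 7]
    transform: identity
    direction: higher-worse
  who5:
    label: "WHO-Five Well-Being Index (raw item sum is multiplied by 4)"
    item_count: 5
    item_levels: [0, 1, 2, 3, 4, 5]
    total_range: [0, 100]
    transform: multiply-by-4
    direction: higher-better

cutoffs:
  gaming_high_min: 4       # high degree of problematic gaming: 4-9
  smfq_case_min: 8         # depression case: SMFQ >= 8
  anxiety_t_min: 65        # anxiety case: T-score >= 65 (+1.5 SD)
  apss_definite_min_items: 1   # psychotic case: >= 1 "yes, definitely" item
  who5_diminished_max: 50  # diminished well-being: WHO-5 <= 50
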