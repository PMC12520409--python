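{
  "outcome_id": "FFHA",
  "factors": [
    {"id": "A1", "label": "Construction without proper construction qualification", "core_category": "A"},
    {"id": "A2", "label": "Illegal and unauthorized construction", "core_category": "A"},
    {"id": "A3", "label": "In violation of instructions, unauthorized construction", "core_category": "A"},
    {"id": "B1", "label": "Ineffective performance of duties by the person in charge of the construction site", "core_category": "B"},
    {"id": "B2", "label": "Inadequate project safety supervision and enforcement", "core_category": "B"},
    {"id": "B3", "label": "Inadequate supervision by administrative departments", "core_category": "B"},
    {"id": "B4", "label": "Inadequate safety system or unclear responsibility", "core_category": "B"},
    {"id": "B5", "label": "Communication and coordination problems", "core_category": "B"},
    {"id": "B6", "label": "Technical and design defects or deficiencies", "core_category": "B"},
    {"id": "B7", "label": "Inadequate elimination of safety hazards", "core_category": "B"},
    {"id": "B8", "label": "Inadequate response to emergencies", "core_category": "B"},
    {"id": "C1", "label": "Non-standard scaffolding", "core_category": "C"},
    {"id": "C2", "label": "Inadequate site lighting", "core_category": "C"},
    {"id": "C3", "label": "Defective work equipment and facilities", "core_category": "C"},
    {"id": "D1", "label": "Inadequate personal protection", "core_category": "D"},
    {"id": "D2", "label": "Failure to post safety warnings and signs", "core_category": "D"},
    {"id": "D3", "label": "Inadequate site safety protection", "core_category": "D"},
    {"id": "E1", "label": "Careless operation", "core_category": "E"},
    {"id": "E2", "label": "Low safety awareness of construction personnel", "core_category": "E"},
    {"id": "E3", "label": "Physical or psychological problems of construction personnel", "core_category": "E"}
  ]
}
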