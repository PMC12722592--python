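[
  {
    "id": "sex-consistency",
    "kind": "sex_consistency",
    "validity": "invalid",
    "error_type": "gender_error",
    "suggestion_policy": "compatible_alternative"
  },
  {
    "id": "age-consistency",
    "kind": "age_consistency",
    "validity": "invalid",
    "error_type": "age_error",
    "suggestion_policy": "compatible_alternative"
  },
  {
    "id": "modality-consistency",
    "kind": "modality_consistency",
    "validity": "invalid",
    "error_type": "mismatched_imaging_modality",
    "suggestion_policy": "compatible_alternative"
  },
  {
    "id": "side-contradiction",
    "kind": "laterality_contradiction",
    "validity": "invalid",
    "error_type": "side_confusion",
    "suggestion_policy": "majority_side"
  },
  {
    "id": "unit-size",
    "kind": "unit_context",
    "params": {"cue": "大小约", "allowed_units": ["cm", "mm"]},
    "validity": "invalid",
    "error_type": "incorrect_measurement_unit",
    "suggestion_policy": "first_allowed_unit"
  },
  {
    "id": "unit-diameter",
    "kind": "unit_context",
    "params": {"cue": "直径约", "allowed_units": ["cm", "mm"]},
    "validity": "invalid",
    "error_type": "incorrect_measurement_unit",
    "suggestion_policy": "first_allowed_unit"
  },
  {
    "id": "unit-attenuation",
    "kind": "unit_context",
    "params": {"cue": "CT值", "allowed_units": ["HU"]},
    "validity": "invalid",
    "error_type": "incorrect_measurement_unit",
    "suggestion_policy": "first_allowed_unit"
  }
]
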