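# A cohort resembling the motivating case study: ~79 surgical patients,
# pathology-derived items only available as free text in the EMR.
n_patients: 79
seed: 11
registry_coverage: 0.95
unstructured_items: [ct_stage, pn_stage, pm_stage,
                     examined_lymph_nodes, circumferential_margin_mm]
per_item_completeness:
  meeting_date: {registry: 0.85, emr: 0.79}
  radiotherapy_start_date: {registry: 0.9, emr: 0.8}
per_item_error:
  chemotherapy: 0.3
  meeting_date: 0.02
emr_extract_noise:
  missing_diagnosis: 0.05
  diagnosis_after_operation: 0.08
  imprecise_code: 0.03
  wrong_procedure_class: 0.01
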