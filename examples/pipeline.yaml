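generator:
  n_patients: 79
  seed: 11
  registry_coverage: 0.95
  unstructured_items: [ct_stage, pn_stage, pm_stage,
                       examined_lymph_nodes, circumferential_margin_mm]
  per_item_error: {chemotherapy: 0.3}
  emr_extract_noise: {missing_diagnosis: 0.05, diagnosis_after_operation: 0.08}
output_dir: report_out
significance_level: 0.05
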