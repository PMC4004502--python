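# Default code lists and mappings. Users may supply their own document with
# the same keys to adapt the indicator set to a local coding system.

# Diagnosis location classes counted as colonic vs rectal carcinoma.
colonic_locations: [colon, rectosigmoid]
rectal_locations: [rectum]

# Procedure classes counting as a resection of the respective kind.
colectomy_codes: [colectomy]
rectum_resection_codes: [rectum_resection]

# Operation-urgency categories counting as elective (after harmonisation).
elective_categories: [elective]

# Harmonisation of source-system urgency categories onto the four registry
# categories. Unlisted categories are left unmapped and reported as a
# standardisation problem.
urgency_mapping:
  elective: elective
  planned: elective
  scheduled: elective
  semi_urgent: urgent
  urgent: urgent
  emergency: acute
  acute: acute
  transfer: urgent
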