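# Default assertion rules for the CAN annotator.
#
# Negation follows the NegEx convention: a pre-trigger negates a mention
# within `scope_tokens` tokens unless a terminator intervenes.
#
# Exclusion rules suppress the recurring false-positive patterns seen in
# clinical notes: third-party (non-patient) subjects, template legends,
# first-aid / patient-instruction boilerplate, section-header fragments,
# and abbreviation-expansion artifacts. They are data: edit or extend this
# file and pass it with --rules.
negation:
  scope_tokens: 6
  triggers:
    - no
    - not
    - denies
    - deny
    - denied
    - without
    - negative for
    - no evidence of
    - no signs of
    - never
  terminators:
    - but
    - however
    - although
    - except
exclusions:
  - rule_id: r1
    kind: non_patient_subject
    scope: sentence
    params:
      kin_tokens: [mother, father, grandmother, grandfather, grandparents, aunt, uncle, stepmother, stepfather]
      history_markers: [per, history, hx, reports, reported, states, stated]
      window_tokens: 6
  - rule_id: r2
    kind: template_pattern
    scope: sentence
    params:
      patterns:
        - '\bA[VO]\s*=\s*alleged\s+(victim|offender)\b'
        - '(?i)^\s*abbreviations\b'
  - rule_id: r3
    kind: phrase_blacklist
    scope: sentence
    params:
      starts_with: ['first aid:']
      contains: ['call 911']
  - rule_id: r4
    kind: section_header
    scope: sentence
    params:
      verbs: [is, are, was, were, be, been, has, have, had, denies, denied, reports,
              reported, states, stated, presents, presented, describes, described,
              discloses, disclosed, notes, noted, says, said, shows, showed]
  - rule_id: r5
    kind: template_pattern
    scope: sentence
    params:
      paren_definition: true
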