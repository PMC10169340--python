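# Diagnosis code lists defining the chronic conditions used for cohort
# eligibility and as model predictors.  Physical conditions use ICD-9-CM
# codes, mental-health conditions ICD-10.  Pattern grammar:
#   - literal code            "714.0", "F43.1"
#   - prefix (trailing x)     "427.3x" matches 427.3 and any 427.3*
#   - bare root               "173" matches any code whose 3-digit root is 173
#   - root range              "140-239" matches any code with root in [140, 239]
# A code matches a list iff it matches at least one include pattern and no
# exclude pattern.
physical:
  code_system: ICD9
  conditions:
    atrial_fibrillation:
      include: ["427.3x"]
    cancer:
      include: ["140-239"]
      exclude: ["173", "209.4x", "209.5x", "209.6x", "209.7x", "209.8x", "209.9x",
                "210-224", "226-229", "232"]
    chronic_lung_disease:
      include: ["491.x", "492.x", "494.x", "495.x", "496.x", "500-505"]
    cad_angina:
      include: ["413.x"]
    cad_mi:
      include: ["412.x"]
    dementia:
      include: ["331.x"]
    diabetes:
      include: ["250.x", "357.2", "362.0", "366.41"]
    epilepsy:
      include: ["345.x"]
    heart_failure:
      include: ["398.91", "402.01", "402.11", "402.91", "404.01", "404.03",
                "404.11", "404.13", "404.91", "404.93", "425.x", "428.x"]
    hypertension:
      include: ["401.x", "402.x", "403.x", "404.x", "405.x"]
    ibd:
      include: ["555.x", "556.x"]
    osteoporosis:
      include: ["733.0x"]
    peripheral_arterial_disease:
      include: ["440.x", "441-442", "443.89", "443.9"]
    rheumatoid_arthritis:
      include: ["714.0"]
    sleep_disorders:
      include: ["327.x"]
      exclude: ["327.35"]
    stroke_history:
      include: ["438.x"]
    venous_thromboembolism:
      include: ["415.x", "453.x"]
mental:
  code_system: ICD10
  conditions:
    alcohol_misuse:
      include: ["F10.x"]
      exclude: ["F10.11", "F10.21"]
    anxiety:
      include: ["F41.x"]
    adhd:
      include: ["F90.x"]
    bipolar:
      include: ["F31.x"]
    depression:
      include: ["F32.x", "F33.x"]
    ptsd:
      include: ["F43.1"]
    schizophrenia:
      include: ["F20.x", "F25.x"]
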