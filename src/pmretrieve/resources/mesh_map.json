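{
  "Female": {"gender": "Female"},
  "Male": {"gender": "Male"},
  "Adult": {"age_category": "Adult"},
  "Young Adult": {"age_category": "Young"},
  "Middle Aged": {"age_category": "Middle age"},
  "Aged": {"age_category": "Aged"},
  "Aged, 80 and over": {"age_category": "Aged 80"},
  "Infant": {"age_category": "Infant"},
  "Infant, Newborn": {"age_category": "Newborn"},
  "Child": {"age_category": "Child"},
  "Child, Preschool": {"age_category": "Preschool"},
  "Adolescent": {"age_category": "Adolescent"},
  "Fetus": {"age_category": "Fetus"}
}
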