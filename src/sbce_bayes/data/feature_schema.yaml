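# Canonical 9-feature categorical coding of a small-bowel capsule endoscopy
# (SBCE) reading. Level code 1 is always the normal/absent condition.
version: 1
features:
  - column: f1
    name: area_affected
    levels: ["normal", "proximal and beyond"]
  - column: f2
    name: distribution_pattern
    levels: ["normal", "patchy", "continuous"]
  - column: f3
    name: mosaic_pattern
    levels: ["absent", "present"]
  - column: f4
    name: fissuring
    levels: ["absent", "present"]
  - column: f5
    name: scalloping
    levels: ["absent", "present"]
  - column: f6
    name: villous_atrophy
    levels: ["absent", "present"]
  - column: f7
    name: nodularity
    levels: ["absent", "present"]
  - column: f8
    name: ulcers
    levels: ["absent", "present"]
  - column: f9
    name: extent_abnormal_mucosa
    levels: ["<50%", ">50%"]
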