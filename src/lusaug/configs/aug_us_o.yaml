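name: aug_us_o
out_size: [128, 128]
transforms:
  - id: B00
    probability: 0.3
  - id: B01
    probability: 0.75
  - id: B02
    probability: 0.5
  - id: B03
    probability: 0.2
  - id: B04
    probability: 0.5
  - id: B05
    probability: 0.5
  - id: B06
    probability: 0.5
  - id: B07
    probability: 0.333
  - id: B08
    probability: 0.333
  - id: B09
    probability: 0.1
  - id: B10
    probability: 0.5
  - id: B11
    probability: 0.5
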