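name: aug_us_d
out_size: [128, 128]
transforms:
  - id: B03
    probability: 0.2
  - id: A02
    probability: 0.8
  - id: B11
    probability: 0.5
  - id: A00
    probability: 1.0
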