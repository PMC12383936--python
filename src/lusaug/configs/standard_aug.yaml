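name: standard_aug
out_size: [128, 128]
transforms:
  - id: A00
    probability: 1.0
  - id: A01
    probability: 0.5
  - id: A02
    probability: 0.8
  - id: A03
    probability: 0.2
  - id: A04
    probability: 0.5
  - id: A05
    probability: 0.1
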