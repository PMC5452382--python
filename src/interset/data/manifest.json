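{
  "description": "bundled demo fixtures: six synthetic histone-mark-like peak sets",
  "genome": {
    "chr1": 50000,
    "chr2": 50000
  },
  "generator": "interset.synthgen",
  "master_seed": 1,
  "n_base_intervals": 90,
  "length_range": [
    150,
    400
  ]
}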