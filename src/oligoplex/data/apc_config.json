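{
  "sizes": {
    "L_obscura": {"endpoint": 322, "qpcr": 72},
    "L_pearmani": {"endpoint": 241, "qpcr": 67},
    "L_bostrychophila": {"endpoint": 184, "qpcr": 96},
    "L_brunnea": {"endpoint": 140, "qpcr": 140},
    "L_decolor": {"endpoint": 99, "qpcr": 99}
  },
  "genomic_sizes": {
    "L_obscura": {"endpoint": 438, "qpcr": 100},
    "L_pearmani": {"endpoint": 351, "qpcr": 115},
    "L_bostrychophila": {"endpoint": 191, "qpcr": 131},
    "L_brunnea": {"endpoint": 140, "qpcr": 140},
    "L_decolor": {"endpoint": 87, "qpcr": 87}
  },
  "inter_spacer_len": 10,
  "min_size_gap": 20
}
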