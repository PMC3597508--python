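{
  "donor_sites": ["GTATGT", "GTAAGT"],
  "branch_sites": ["TACTAAC"],
  "acceptor_sites": ["TAG", "CAG"],
  "pseudocount": 0.5,
  "threshold_fraction": 0.6,
  "min_intron_len": 40,
  "max_intron_len": 1000,
  "branch_to_acceptor_window": [10, 200]
}
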