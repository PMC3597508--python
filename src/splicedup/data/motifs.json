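{
  "description": "Degenerate consensus patterns for Ski7/Hbs1 diagnostic motifs. Versioned data distilled by the implementers from multiple alignments of fungal Ski7/Hbs1 homologs; patterns are landmarks, not profile HMMs.",
  "motifs": [
    {"id": "NTD", "pattern": "FDELVRQWNP", "threshold": 0.85, "special_positions": {}, "required_for": []},
    {"id": "S1", "pattern": "MSDFRKLAE", "threshold": 0.85, "special_positions": {}, "required_for": ["SKI7"]},
    {"id": "S2", "pattern": "WQDLTPEHR", "threshold": 0.85, "special_positions": {}, "required_for": ["SKI7"]},
    {"id": "S3", "pattern": "YKEANPLRF", "threshold": 0.85, "special_positions": {}, "required_for": ["SKI7"]},
    {"id": "H1", "pattern": "LNEYDWKQP", "threshold": 0.85, "special_positions": {}, "required_for": ["HBS1"]},
    {"id": "G1", "pattern": "GHVDHGKT", "threshold": 0.85, "special_positions": {}, "required_for": ["HBS1"]},
    {"id": "G2", "pattern": "RGITINTA", "threshold": 0.85, "special_positions": {}, "required_for": ["HBS1"]},
    {"id": "G3", "pattern": "DTPGHV", "threshold": 1.0, "special_positions": {"catalytic_his": 4}, "required_for": ["HBS1"]},
    {"id": "G4", "pattern": "NKIDLV", "threshold": 1.0, "special_positions": {}, "required_for": ["HBS1"]},
    {"id": "G5", "pattern": "GSALKALE", "threshold": 0.85, "special_positions": {}, "required_for": ["HBS1"]},
    {"id": "S1_PRIME", "pattern": "MTEYKLNN", "threshold": 1.0, "special_positions": {}, "required_for": [], "optional": true}
  ]
}
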