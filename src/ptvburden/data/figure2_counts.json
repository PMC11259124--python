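{
  "case_label": "HCMP cohort",
  "case_n": 2366,
  "case_carriers": 36,
  "controls": [
    {"label": "gnomAD v4.0 East Asian", "n": 22448, "carriers": 16},
    {"label": "KoGES + KOVA2", "n": 10305, "carriers": 15},
    {"label": "Internal exomes", "n": 5996, "carriers": 8}
  ],
  "combined_label": "Combined controls"
}
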