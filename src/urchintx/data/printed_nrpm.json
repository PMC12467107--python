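[
  {"gene": "GABA-B1", "species": "M. franciscanus", "stage": "EC", "nrpm": 1.778},
  {"gene": "GABA-B2", "species": "M. franciscanus", "stage": "EC", "nrpm": 0.829},
  {"gene": "nAChR-b3", "species": "M. franciscanus", "stage": "EC", "nrpm": 2.9},
  {"gene": "nAChR-a2", "species": "M. franciscanus", "stage": "EC", "nrpm": 38.0},
  {"gene": "nAChR-a3", "species": "M. franciscanus", "stage": "EC", "nrpm": 5203.0},
  {"gene": "nAChR-a7", "species": "M. franciscanus", "stage": "EC", "nrpm": 0.035},
  {"gene": "nAChR-a10", "species": "M. franciscanus", "stage": "EC", "nrpm": 1167.0},
  {"gene": "nAChR-b3", "species": "P. lividus", "stage": "EC", "nrpm": 0.05},
  {"gene": "TPH", "species": "S. purpuratus", "stage": "LC", "nrpm": 0.22},
  {"gene": "HDC", "species": "S. purpuratus", "stage": "LC", "nrpm": 1.78},
  {"gene": "H1", "species": "S. purpuratus", "stage": "EC", "nrpm": 0.0447},
  {"gene": "H2", "species": "M. franciscanus", "stage": "EC", "nrpm": 0.377},
  {"gene": "H3", "species": "S. purpuratus", "stage": "EC", "nrpm": 0.483},
  {"gene": "GABA-B1", "species": "S. purpuratus", "stage": "EC", "nrpm": 0.4373},
  {"gene": "GAT2", "species": "M. franciscanus", "stage": "EC", "nrpm": 1.15},
  {"gene": "GAT2", "species": "L. variegatus", "stage": "EC", "nrpm": 0.45}
]
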