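{
  "M. franciscanus": {
    "EC": {"native": "Egg", "hpf": 0.0},
    "LC": {"native": "7 hpf", "hpf": 7.0},
    "EB": null,
    "LB": {"native": "16 hpf", "hpf": 16.0},
    "EG": {"native": "29 hpf", "hpf": 29.0}
  },
  "P. lividus": {
    "EC": {"native": "Egg", "hpf": 0.0},
    "LC": null,
    "EB": {"native": "12 hpf", "hpf": 12.0},
    "LB": {"native": "18 hpf", "hpf": 18.0},
    "EG": {"native": "24 hpf", "hpf": 24.0}
  },
  "L. variegatus": {
    "EC": {"native": "1 hpf", "hpf": 1.0},
    "LC": {"native": "2.5 hpf", "hpf": 2.5},
    "EB": {"native": "4 hpf", "hpf": 4.0},
    "LB": {"native": "7 hpf", "hpf": 7.0},
    "EG": {"native": "12 hpf", "hpf": 12.0}
  },
  "S. purpuratus": {
    "EC": {"native": "Egg", "hpf": 0.0},
    "LC": {"native": "10 hpf", "hpf": 10.0},
    "EB": {"native": "18 hpf", "hpf": 18.0},
    "LB": {"native": "24 hpf", "hpf": 24.0},
    "EG": {"native": "30 hpf", "hpf": 30.0}
  }
}
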