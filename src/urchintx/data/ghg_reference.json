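{
  "M. franciscanus": {"EC": 559.068, "LC": 2711.161, "LB": 1443.028, "EG": 2004.563},
  "P. lividus": {"EC": 97.394, "EB": 108.306, "LB": 91.15, "EG": 99.959},
  "L. variegatus": {"EC": 4056.580, "LC": 5140.630, "EB": 4184.16, "LB": 4166.32, "EG": 7714.20},
  "S. purpuratus": {"EC": 1388.124, "LC": 5121.778, "EB": 4838.051, "LB": 6287.357, "EG": 7629.709}
}
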