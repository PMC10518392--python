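{
  "AI": {
    "L": {"A": 94, "B": 9, "C": 1, "D": 0, "E": 0},
    "R": {"A": 83, "B": 18, "C": 3, "D": 0, "E": 0}
  },
  "Freehand": {
    "L": {"A": 73, "B": 27, "C": 4, "D": 0, "E": 0},
    "R": {"A": 62, "B": 29, "C": 11, "D": 2, "E": 0}
  }
}
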