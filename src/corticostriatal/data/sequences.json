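{
  "comment": "Synthetic reconstruction of the eight three-movement sequences of the oculomotor sequence task. The exact figure-level triple assignment is not public; this table satisfies every textual constraint: all 2x2x2 binary branches covered, hemifield(S1,S2,S5,S6)=upper and (S3,S4,S7,S8)=lower, every direction used by at least two sequences, S2=(center-L,left-up,upper-R), S4=(center-R,right-down,lower-L), S5=(center-R,right-up,upper-R), S1 and S8 start with center-R.",
  "directions": [
    "center-L", "center-R",
    "left-up", "left-down", "right-up", "right-down",
    "upper-L", "upper-R", "lower-L", "lower-R"
  ],
  "decision_points": ["center", "upwards", "downwards", "upper", "lower"],
  "sequences": [
    {"id": 1, "moves": [1, 4, 6], "hemifield": "upper"},
    {"id": 2, "moves": [0, 2, 7], "hemifield": "upper"},
    {"id": 3, "moves": [0, 3, 9], "hemifield": "lower"},
    {"id": 4, "moves": [1, 5, 8], "hemifield": "lower"},
    {"id": 5, "moves": [1, 4, 7], "hemifield": "upper"},
    {"id": 6, "moves": [0, 2, 6], "hemifield": "upper"},
    {"id": 7, "moves": [0, 3, 8], "hemifield": "lower"},
    {"id": 8, "moves": [1, 5, 9], "hemifield": "lower"}
  ]
}
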