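{
  "tm_ranges": [
    {"tm": 1, "start_resid": 44, "start_label": "1.33", "end_resid": 70, "end_label": "1.59"},
    {"tm": 2, "start_resid": 77, "start_label": "2.38", "end_resid": 104, "end_label": "2.65"},
    {"tm": 3, "start_resid": 112, "start_label": "3.22", "end_resid": 145, "end_label": "3.55"},
    {"tm": 4, "start_resid": 150, "start_label": "4.33", "end_resid": 181, "end_label": "4.64"},
    {"tm": 5, "start_resid": 202, "start_label": "5.32", "end_resid": 237, "end_label": "5.67"},
    {"tm": 6, "start_resid": 245, "start_label": "6.24", "end_resid": 280, "end_label": "6.59"},
    {"tm": 7, "start_resid": 288, "start_label": "7.29", "end_resid": 315, "end_label": "7.56"}
  ],
  "loop_ranges": {
    "ECL1": [105, 111],
    "ECL2": [182, 201],
    "ECL3": [281, 287],
    "ICL1": [71, 76],
    "ICL2": [146, 149],
    "ICL3": [238, 244]
  }
}
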