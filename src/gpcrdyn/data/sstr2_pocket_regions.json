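{
  "top": [102, 103, 106, 107, 192, 194, 195, 200, 201, 281, 282, 284, 285, 286],
  "middle": [92, 99, 100, 118, 121, 205, 208, 272, 275, 276, 279, 280, 291, 294, 298],
  "bottom": [122, 126, 177, 302]
}
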