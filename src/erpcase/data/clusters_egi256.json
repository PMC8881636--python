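{
  "layout": "HCGSN 256-lead geodesic net, 1-based sensor labels (label 257 is the vertex reference)",
  "posterior": {
    "name": "occipito-parietal (EPN)",
    "labels": [106, 107, 108, 113, 114, 115, 116, 117, 121, 122, 123, 124,
               125, 126, 133, 134, 135, 136, 137, 138, 139, 145, 146, 147,
               148, 149, 150, 151, 156, 157, 158, 159, 160, 165, 166, 167,
               168, 169, 174, 175, 176]
  },
  "central": {
    "name": "centro-parietal (LPP)",
    "labels": [6, 7, 8, 9, 15, 16, 17, 23, 24, 30, 42, 43, 44, 45, 51, 52,
               53, 59, 60, 79, 80, 81, 89, 130, 131, 132, 143, 144, 155,
               183, 184, 185, 186, 196, 197, 198, 206, 207, 215, 257]
  }
}
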