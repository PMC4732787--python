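{
  "label": "5-cell",
  "tg_edges": [50, 100, 150, 200],
  "nonhdl_edges": [],
  "tg_max": 400,
  "factors": [
    [2.71],
    [4.11],
    [5.19],
    [5.70],
    [6.21]
  ]
}
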