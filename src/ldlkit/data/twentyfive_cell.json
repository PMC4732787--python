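{
  "label": "25-cell",
  "tg_edges": [50, 100, 150, 200],
  "nonhdl_edges": [100, 130, 160, 190],
  "tg_max": 400,
  "factors": [
    [2.8, 2.7, 2.5, 2.7, 2.1],
    [4.2, 4.2, 4.0, 3.9, 3.8],
    [5.5, 5.5, 5.1, 4.9, 4.5],
    [6.3, 6.1, 5.9, 5.5, 4.9],
    [7.1, 6.7, 6.4, 6.2, 5.5]
  ]
}
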