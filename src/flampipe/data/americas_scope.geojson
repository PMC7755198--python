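{
  "type": "Polygon",
  "coordinates": [
    [
      [-170.0, -60.0],
      [-25.0, -60.0],
      [-25.0, 75.0],
      [-170.0, 75.0],
      [-170.0, -60.0]
    ]
  ]
}
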