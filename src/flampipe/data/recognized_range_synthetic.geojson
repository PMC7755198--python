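{
  "type": "MultiPolygon",
  "coordinates": [
    [[[-92.0, 19.0], [-73.0, 19.0], [-73.0, 23.5], [-92.0, 23.5], [-92.0, 19.0]]],
    [[[-78.9, 23.6], [-72.5, 23.6], [-72.5, 27.3], [-78.9, 27.3], [-78.9, 23.6]]],
    [[[-67.5, 13.0], [-59.0, 13.0], [-59.0, 19.0], [-67.5, 19.0], [-67.5, 13.0]]],
    [[[-75.0, 9.0], [-62.0, 9.0], [-62.0, 12.8], [-75.0, 12.8], [-75.0, 9.0]]],
    [[[-92.5, -1.6], [-88.9, -1.6], [-88.9, 0.8], [-92.5, 0.8], [-92.5, -1.6]]]
  ]
}
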