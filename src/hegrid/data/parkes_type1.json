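{
  "name": "Parkes",
  "version": "type1-consensus",
  "unit": "mg/dL",
  "domain": [[0, 550], [0, 550]],
  "resolution": 0.1,
  "meta": {
    "description": "Parkes (consensus) error grid, type 1 diabetes variant; zone polygons assembled from the published boundary vertex lists.",
    "axes": "x = reference (SMBG), y = measured (CGM), mg/dL"
  },
  "zones": [
    {"label": "A", "polygon": [[0, 0], [50, 0], [50, 30], [170, 145], [385, 300], [550, 450], [550, 550], [430, 550], [280, 380], [140, 170], [30, 50], [0, 50], [0, 0]]},
    {"label": "B", "polygon": [[0, 50], [30, 50], [140, 170], [280, 380], [430, 550], [260, 550], [70, 110], [50, 80], [30, 60], [0, 60], [0, 50]]},
    {"label": "B", "polygon": [[50, 0], [120, 0], [120, 30], [260, 130], [550, 250], [550, 450], [385, 300], [170, 145], [50, 30], [50, 0]]},
    {"label": "C", "polygon": [[0, 60], [30, 60], [50, 80], [70, 110], [260, 550], [125, 550], [80, 215], [50, 125], [25, 100], [0, 100], [0, 60]]},
    {"label": "C", "polygon": [[120, 0], [250, 0], [250, 40], [550, 150], [550, 250], [260, 130], [120, 30], [120, 0]]},
    {"label": "D", "polygon": [[0, 100], [25, 100], [50, 125], [80, 215], [125, 550], [50, 550], [35, 155], [0, 150], [0, 100]]},
    {"label": "D", "polygon": [[250, 0], [550, 0], [550, 150], [250, 40], [250, 0]]},
    {"label": "E", "polygon": [[0, 150], [35, 155], [50, 550], [0, 550], [0, 150]]}
  ]
}
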