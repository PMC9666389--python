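{
  "name": "Clarke",
  "version": "1987-published",
  "unit": "mg/dL",
  "domain": [[0, 400], [0, 400]],
  "resolution": 0.1,
  "meta": {
    "description": "Clarke error grid for blood glucose meter evaluation; zone polygons derived analytically from the published zone rule set (A: within 20% of reference or both <=70 mg/dL; E: opposite extremes; C: overcorrection regions; D: dangerous failure to detect; else B).",
    "axes": "x = reference (SMBG), y = measured (CGM), mg/dL"
  },
  "zones": [
    {"label": "A", "polygon": [[0, 0], [0, 70], [58.333333333333336, 70], [333.3333333333333, 400], [400, 400], [400, 320], [70, 56], [70, 0], [0, 0]]},
    {"label": "B", "polygon": [[70, 84], [70, 180], [290, 400], [333.3333333333333, 400], [70, 84]]},
    {"label": "B", "polygon": [[70, 0], [130, 0], [180, 70], [240, 70], [240, 180], [400, 180], [400, 320], [70, 56], [70, 0]]},
    {"label": "C", "polygon": [[70, 180], [290, 400], [70, 400], [70, 180]]},
    {"label": "C", "polygon": [[130, 0], [180, 0], [180, 70], [130, 0]]},
    {"label": "D", "polygon": [[0, 70], [58.333333333333336, 70], [70, 84], [70, 180], [0, 180], [0, 70]]},
    {"label": "D", "polygon": [[240, 70], [400, 70], [400, 180], [240, 180], [240, 70]]},
    {"label": "E", "polygon": [[0, 180], [70, 180], [70, 400], [0, 400], [0, 180]]},
    {"label": "E", "polygon": [[180, 0], [400, 0], [400, 70], [180, 70], [180, 0]]}
  ]
}
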