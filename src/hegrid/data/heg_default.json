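{
  "name": "HEG",
  "version": "0.1.0-reconstructed",
  "unit": "mmol/L",
  "domain": [[0.0, 12.0], [0.0, 12.0]],
  "resolution": 0.1,
  "meta": {
    "description": "Hypoglycaemia error grid for congenital hyperinsulinism, reconstructed from the published figure structure: hypoglycaemia cutoff 3.5 mmol/L, action cutoff 4.0 mmol/L, risk constant beyond 4.0 mmol/L on both axes, angled slight/moderate boundary across the false-negative corner. Drop in the authors' published boundary file to replace this reconstruction.",
    "provenance": "reconstructed",
    "axes": "x = SMBG (reference), y = CGM, mmol/L"
  },
  "zones": [
    {"label": "A", "polygon": [[0.0, 0.0], [4.0, 0.0], [4.0, 3.5], [0.0, 3.5], [0.0, 0.0]]},
    {"label": "A", "polygon": [[3.5, 3.5], [12.0, 3.5], [12.0, 12.0], [3.5, 12.0], [3.5, 3.5]]},
    {"label": "B", "polygon": [[4.0, 0.0], [12.0, 0.0], [12.0, 3.5], [4.0, 3.5], [4.0, 0.0]]},
    {"label": "B", "polygon": [[3.0, 3.5], [3.5, 3.5], [3.5, 4.0], [3.0, 3.5]]},
    {"label": "C", "polygon": [[0.0, 3.5], [3.0, 3.5], [3.5, 4.0], [3.5, 12.0], [0.0, 12.0], [0.0, 3.5]]}
  ]
}
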