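{
  "description": "Bundled benchmark: per-class accuracies of the six classifier families on the four experiment variants of the reference 63-patient study. Rows follow 'classifiers', columns follow 'classes'.",
  "classes": ["negative", "neutral", "positive_partial", "positive_complete"],
  "classifiers": ["kNN", "LVQNN", "MLPI", "MLPII", "RBFNN", "PNN"],
  "experiments": {
    "original": [
      [0.0,   0.167, 0.741, 0.893],
      [0.0,   1.0,   1.0,   0.929],
      [1.0,   0.667, 0.778, 0.893],
      [0.5,   0.5,   0.889, 0.893],
      [0.0,   0.167, 0.444, 0.964],
      [0.0,   0.333, 0.704, 0.750]
    ],
    "smote": [
      [0.125, 0.417, 0.630, 0.893],
      [1.0,   1.0,   1.0,   1.0],
      [0.5,   0.5,   0.778, 0.930],
      [1.0,   0.917, 0.852, 0.930],
      [0.25,  0.667, 0.444, 0.393],
      [0.375, 0.889, 0.630, 0.679]
    ],
    "pca": [
      [0.0,   0.167, 0.741, 0.893],
      [0.0,   1.0,   1.0,   0.929],
      [0.5,   0.5,   0.778, 0.929],
      [0.5,   0.5,   0.889, 0.893],
      [0.0,   0.333, 0.667, 0.464],
      [0.0,   0.167, 0.778, 0.821]
    ],
    "smote_pca": [
      [0.5,   0.67,  0.630, 0.893],
      [1.0,   1.0,   0.963, 1.0],
      [0.125, 0.833, 0.704, 0.964],
      [0.5,   0.833, 0.815, 0.964],
      [0.375, 0.417, 0.741, 0.714],
      [0.625, 0.583, 0.556, 0.679]
    ]
  }
}
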