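[
  {
    "algorithm": "AIR Warp",
    "axes": {
      "warp_model": [1, 2, 3],
      "blur": [11, 15, 17, 19, 25],
      "model": [6, 7, 9],
      "cost": [1, 3]
    }
  },
  {
    "algorithm": "AIR Linear",
    "axes": {
      "blur": [11, 15, 17, 19, 25],
      "model": [6, 7, 9],
      "cost": [1, 3]
    }
  },
  {
    "algorithm": "FSL FLIRT",
    "axes": {
      "interpolation": ["trilinear", "nearestnbr", "sinc"],
      "dof": [6, 7, 8, 12],
      "cost": ["mutualinfo", "corratio", "normcorr", "normmi", "leastsq"]
    }
  },
  {
    "algorithm": "MINC Tracc",
    "axes": {
      "dof": [3, 6, 7, 9, 10, 12]
    }
  }
]
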