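{
  "_note": "Default resting-state network centers (MNI mm) in the style of the resting-state literature. These are editable convenience defaults shipped with the package, not values taken from any specific study; replace them with your own coordinates for real analyses.",
  "radius_mm": 15.0,
  "networks": [
    {"name": "pDMN", "centers": [[0, -52, 26], [-46, -66, 30], [50, -62, 28]]},
    {"name": "aDMN", "centers": [[0, 52, -6], [-24, 34, 46], [26, 34, 44]]},
    {"name": "DAN", "centers": [[-24, -8, 50], [24, -8, 50], [-26, -62, 52], [26, -62, 52]]},
    {"name": "VAN", "centers": [[-54, -46, 20], [54, -46, 20], [48, 22, 10]]},
    {"name": "FPN", "centers": [[-44, 36, 20], [44, 36, 20], [-48, -50, 48], [48, -50, 48]]},
    {"name": "SMN", "centers": [[-38, -22, 56], [38, -22, 56], [0, -10, 54]]}
  ]
}
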