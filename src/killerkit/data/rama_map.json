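{
  "version": "1.0",
  "comment": "Coarse rectangular Ramachandran region map (a documented simplification of MolProbity-style contours). Each rectangle is [phi_min, phi_max, psi_min, psi_max] in degrees; classification: favored if inside any favored rectangle, else allowed if inside any allowed rectangle, else outlier. Sub-maps: general, glycine, proline, preproline.",
  "general": {
    "favored": [
      [-160, -20, -80, -5],
      [-180, -45, 90, 180],
      [-180, -45, -180, -150]
    ],
    "allowed": [
      [-180, 0, -100, 15],
      [-180, -25, 70, 180],
      [-180, -25, -180, -130],
      [40, 80, 20, 80]
    ]
  },
  "glycine": {
    "favored": [
      [-160, -20, -80, -5],
      [-180, -45, 90, 180],
      [-180, -45, -180, -150],
      [20, 160, -5, 80],
      [45, 180, 150, 180],
      [45, 180, -180, -90]
    ],
    "allowed": [
      [-180, 0, -100, 15],
      [-180, -25, 70, 180],
      [-180, -25, -180, -130],
      [0, 180, -25, 100],
      [25, 180, 130, 180],
      [25, 180, -180, -70]
    ]
  },
  "proline": {
    "favored": [
      [-100, -30, -60, -10],
      [-100, -30, 110, 180]
    ],
    "allowed": [
      [-120, -10, -80, 10],
      [-120, -10, 90, 180],
      [-120, -10, -180, -170]
    ]
  },
  "preproline": {
    "favored": [
      [-160, -20, -80, -5],
      [-180, -45, 90, 180],
      [-180, -45, -180, -150]
    ],
    "allowed": [
      [-180, 0, -100, 15],
      [-180, -25, 70, 180],
      [-180, -25, -180, -130]
    ]
  }
}
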