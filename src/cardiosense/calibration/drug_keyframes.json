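{
  "_meta": {
    "description": "Default drug-effect keyframes for the synthetic generator. Each anchor list is [time_h, percent_of_predrug] for the force and cell-index channels, or [time_h, multiplicative_factor] for beat-duration widening and interval-jitter inflation. Landmark anchors reproduce the reported dose/time responses of the device; anchors marked 'synthetic' in notes are invented fill-ins where only qualitative trends were reported.",
    "doses_are_nmol_per_L": true
  },
  "verapamil": {
    "force": {
      "150": [[0, 100], [4, 90], [8, 100], [24, 100]],
      "300": [[0, 100], [12, 45], [24, 51]],
      "500": [[0, 100], [4, 1.5], [12, 1.5], [24, 15]],
      "1000": [[0, 100], [2, 0], [13, 0], [14, 1.5], [24, 5.5]]
    },
    "ci": {
      "150": [[0, 100], [12, 82], [24, 90]],
      "300": [[0, 100], [12, 74], [24, 84]],
      "500": [[0, 100], [12, 70], [16, 72], [24, 78]],
      "1000": [[0, 100], [12, 65], [24, 75]]
    },
    "duration_factor": {},
    "jitter_factor": {},
    "notes": "150 nmol/L force dip (90% at 4 h) and the recovery endpoints for 150/300/500 nmol/L CI are synthetic fill-ins; all other anchors are reported landmarks. The 150 nmol/L CI minimum time (12 h) is assumed by analogy with the other doses."
  },
  "e4031": {
    "force": {
      "5": [[0, 100], [24, 100]],
      "10": [[0, 100], [24, 100]],
      "20": [[0, 100], [24, 100]],
      "30": [[0, 100], [24, 100]]
    },
    "ci": {
      "5": [[0, 100], [12, 86], [24, 78]],
      "10": [[0, 100], [12, 80], [24, 72]],
      "20": [[0, 100], [12, 74], [24, 66.5]],
      "30": [[0, 100], [12, 70], [24, 64]]
    },
    "duration_factor": {
      "30": [[0, 1.0], [12, 1.5], [24, 1.4]]
    },
    "jitter_factor": {
      "30": [[0, 1.0], [12, 6.0], [24, 3.0]]
    },
    "notes": "hERG block leaves contraction force unchanged; the CI endpoints at 10/20/30 nmol/L are reported landmarks, the 5 nmol/L endpoint and all 12 h midpoints are synthetic fill-ins. Duration widening peaks at 12 h (QT-prolongation analog) and interval jitter inflates to 12 h then eases without full recovery; factor magnitudes are synthetic."
  }
}
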