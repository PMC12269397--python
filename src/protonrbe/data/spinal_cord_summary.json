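{
  "description": "Summary dose-response parameters for the rat cervical spinal cord (endpoint: paresis grade 2 within 300 days). Protons delivered in 6 daily fractions at four depths of a 6 cm spread-out Bragg peak; BED50 and alpha/beta estimated jointly from 1-, 2- and 6-fraction data. The photon reference is a historical 6-fraction experiment with the same setup. Values are (estimate, standard error); cl90 entries are published 90% confidence limits.",
  "endpoint": "paresis grade 2",
  "horizon_days": 300,
  "n_fractions_reference": 6,
  "photon": {
    "ed50_6fx": [57.0, 2.0],
    "bed50": [244.9, 24.3],
    "bed50_cl90": [208.2, 293.3],
    "alpha_beta": [2.8, 0.4],
    "alpha_beta_cl90": [2.2, 3.5]
  },
  "positions": [
    {
      "position_mm": 35,
      "region": "plateau",
      "let_d": 1.4,
      "ed50_6fx": [51.3, 0.7],
      "ed50_6fx_cl90": [49.7, 52.6],
      "bed50": [277.6, 84.9],
      "bed50_cl90": [182.9, 633.1],
      "alpha_beta": [2.0, 0.7],
      "alpha_beta_cl90": [0.8, 3.3],
      "dose_levels_6fx": [48.0, 49.5, 51.0, 52.5, 54.0, 55.5]
    },
    {
      "position_mm": 100,
      "region": "sobp",
      "let_d": 2.7,
      "ed50_6fx": [48.8, 1.1],
      "ed50_6fx_cl90": [45.8, 54.0],
      "bed50": [316.0, 157.6],
      "bed50_cl90": [175.7, 4941.8],
      "alpha_beta": [1.5, 0.9],
      "alpha_beta_cl90": [0.1, 3.0],
      "dose_levels_6fx": [43.0, 44.5, 46.0, 47.5, 49.0, 50.5, 52.0, 53.5]
    },
    {
      "position_mm": 120,
      "region": "sobp",
      "let_d": 3.9,
      "ed50_6fx": [46.2, 0.5],
      "ed50_6fx_cl90": [45.1, 47.4],
      "bed50": [130.9, 18.1],
      "bed50_cl90": [106.4, 175.0],
      "alpha_beta": [4.2, 0.8],
      "alpha_beta_cl90": [2.9, 5.6],
      "dose_levels_6fx": [42.5, 44.0, 45.5, 47.0, 48.5, 50.0]
    },
    {
      "position_mm": 127,
      "region": "sobp",
      "let_d": 5.5,
      "ed50_6fx": [43.3, 0.6],
      "ed50_6fx_cl90": [42.0, 44.5],
      "bed50": [138.2, 19.0],
      "bed50_cl90": [111.8, 184.1],
      "alpha_beta": [3.3, 0.6],
      "alpha_beta_cl90": [2.3, 4.4],
      "dose_levels_6fx": [40.0, 41.5, 43.0, 44.5, 46.0, 47.5]
    }
  ]
}
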