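{
  "calibration": {
    "synthA": {
      "down": {
        "alg1": {
          "max_retained_nominal": 4.296040469427276e-07,
          "n_permutations": 100,
          "null_quantile": 0.01,
          "seed": 1989427044,
          "threshold_adjusted": 0.29270977981397794,
          "threshold_nominal": 0.015474381975407268
        },
        "alg2": {
          "max_retained_nominal": 2.4621501858516004e-05,
          "n_permutations": 100,
          "null_quantile": 0.01,
          "seed": 1989427044,
          "threshold_adjusted": 0.2605840521705682,
          "threshold_nominal": 0.013029202608528408
        },
        "alg3": {
          "max_retained_nominal": 2.3687550298795466e-06,
          "n_permutations": 100,
          "null_quantile": 0.01,
          "seed": 1989427044,
          "threshold_adjusted": 0.22865340454434652,
          "threshold_nominal": 0.011432670227217325
        }
      }
    }
  },
  "candidates": {
    "fisher": [
      {
        "consensus": true,
        "mirna": "miR-003",
        "supports": {
          "synthA:down": [
            "alg1",
            "alg2",
            "alg3"
          ]
        }
      },
      {
        "consensus": true,
        "mirna": "miR-013",
        "supports": {
          "synthA:down": [
            "alg1",
            "alg2",
            "alg3"
          ]
        }
      },
      {
        "consensus": true,
        "mirna": "miR-015",
        "supports": {
          "synthA:down": [
            "alg1",
            "alg2",
            "alg3"
          ]
        }
      }
    ],
    "ks": [
      {
        "consensus": true,
        "mirna": "miR-013",
        "supports": {
          "synthA": [
            "alg1",
            "alg2",
            "alg3"
          ]
        }
      }
    ]
  },
  "config": {
    "alpha": 0.05,
    "consensus_scope": "list",
    "datasets": [
      {
        "expression": "expression.tsv",
        "id": "synthA",
        "labels": "labels.tsv"
      }
    ],
    "expressed": "expressed_mirnas.txt",
    "ks": {
      "alpha": 0.05,
      "min_targets": 10,
      "presence_fraction": 0.6,
      "presence_quantile": 0.25
    },
    "min_algorithms": 2,
    "min_genes": 30,
    "n_perm": 100,
    "null_quantile": 0.01,
    "run_ks": true,
    "seed": 17,
    "targets": "predictions.tsv",
    "targets_format": "long_tsv"
  },
  "datasets": {
    "synthA": {
      "ks_n_retained": 247,
      "n_down": 60,
      "n_genes": 300,
      "n_samples_neg": 12,
      "n_samples_pos": 12,
      "n_up": 2,
      "qualifies_down": true,
      "qualifies_up": false
    }
  },
  "inputs_sha256": {
    "expressed_mirnas.txt": "74cfe2d797e69010e8651c89800dbcdaecab40c4028089afe8d9ad2407e60718",
    "expression.tsv": "5d3fc6ae0be96fdec364cf0137374d6a2d393d5c5b49a5458cd7252153f54b6b",
    "labels.tsv": "0e1b4f7a7d543469536de977e6919f1fc6c07962f4d51521417eac60f7dac2e0",
    "predictions.tsv": "f371ec19e8a1d56dcffa58edeb378917b4ebc21b0ce38624f32d157144578768"
  },
  "occurrence": {
    "fisher": {
      "synthA": {
        "miR-003": "x(3)",
        "miR-013": "x(3)",
        "miR-015": "x(3)"
      }
    },
    "ks": {
      "synthA": {
        "miR-013": "x(3)"
      }
    }
  },
  "versions": {
    "mirenrich": "0.1.0",
    "numpy": "2.4.6",
    "pandas": "2.3.3"
  }
}
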