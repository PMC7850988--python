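{
  "title": "perturbsig analysis reports",
  "BaselineReport": {
    "$defs": {
      "PermutationTestReport": {
        "properties": {
          "pseudo_F": {
            "title": "Pseudo F",
            "type": "number"
          },
          "p_value": {
            "title": "P Value",
            "type": "number"
          },
          "n_permutations": {
            "title": "N Permutations",
            "type": "integer"
          }
        },
        "required": [
          "pseudo_F",
          "p_value",
          "n_permutations"
        ],
        "title": "PermutationTestReport",
        "type": "object"
      }
    },
    "properties": {
      "analysis": {
        "default": "baseline",
        "title": "Analysis",
        "type": "string"
      },
      "config": {
        "additionalProperties": true,
        "title": "Config",
        "type": "object"
      },
      "input_hashes": {
        "additionalProperties": {
          "type": "string"
        },
        "title": "Input Hashes",
        "type": "object"
      },
      "n_samples": {
        "title": "N Samples",
        "type": "integer"
      },
      "n_taxa": {
        "title": "N Taxa",
        "type": "integer"
      },
      "delta": {
        "title": "Delta",
        "type": "number"
      },
      "alr_reference": {
        "title": "Alr Reference",
        "type": "string"
      },
      "alr_dim": {
        "title": "Alr Dim",
        "type": "integer"
      },
      "cv_auroc": {
        "title": "Cv Auroc",
        "type": "number"
      },
      "pooled_auroc": {
        "title": "Pooled Auroc",
        "type": "number"
      },
      "empirical_p": {
        "title": "Empirical P",
        "type": "number"
      },
      "n_signature_features": {
        "title": "N Signature Features",
        "type": "integer"
      },
      "signature_features": {
        "items": {
          "type": "string"
        },
        "title": "Signature Features",
        "type": "array"
      },
      "permanova": {
        "$ref": "#/$defs/PermutationTestReport"
      }
    },
    "required": [
      "config",
      "input_hashes",
      "n_samples",
      "n_taxa",
      "delta",
      "alr_reference",
      "alr_dim",
      "cv_auroc",
      "pooled_auroc",
      "empirical_p",
      "n_signature_features",
      "signature_features",
      "permanova"
    ],
    "title": "BaselineReport",
    "type": "object"
  },
  "PerturbationReport": {
    "$defs": {
      "PermutationTestReport": {
        "properties": {
          "pseudo_F": {
            "title": "Pseudo F",
            "type": "number"
          },
          "p_value": {
            "title": "P Value",
            "type": "number"
          },
          "n_permutations": {
            "title": "N Permutations",
            "type": "integer"
          }
        },
        "required": [
          "pseudo_F",
          "p_value",
          "n_permutations"
        ],
        "title": "PermutationTestReport",
        "type": "object"
      }
    },
    "properties": {
      "analysis": {
        "default": "perturbation",
        "title": "Analysis",
        "type": "string"
      },
      "config": {
        "additionalProperties": true,
        "title": "Config",
        "type": "object"
      },
      "input_hashes": {
        "additionalProperties": {
          "type": "string"
        },
        "title": "Input Hashes",
        "type": "object"
      },
      "n_samples": {
        "title": "N Samples",
        "type": "integer"
      },
      "n_taxa": {
        "title": "N Taxa",
        "type": "integer"
      },
      "n_groups": {
        "title": "N Groups",
        "type": "integer"
      },
      "delta": {
        "title": "Delta",
        "type": "number"
      },
      "alr_reference": {
        "title": "Alr Reference",
        "type": "string"
      },
      "alr_dim": {
        "title": "Alr Dim",
        "type": "integer"
      },
      "cv_auroc": {
        "title": "Cv Auroc",
        "type": "number"
      },
      "pooled_auroc": {
        "title": "Pooled Auroc",
        "type": "number"
      },
      "empirical_p": {
        "title": "Empirical P",
        "type": "number"
      },
      "n_signature_features": {
        "title": "N Signature Features",
        "type": "integer"
      },
      "signature_features": {
        "items": {
          "type": "string"
        },
        "title": "Signature Features",
        "type": "array"
      },
      "permanova": {
        "$ref": "#/$defs/PermutationTestReport"
      },
      "permdisp": {
        "$ref": "#/$defs/PermutationTestReport"
      },
      "n_pairwise_comparisons": {
        "title": "N Pairwise Comparisons",
        "type": "integer"
      },
      "n_nonsignificant_pairs": {
        "title": "N Nonsignificant Pairs",
        "type": "integer"
      },
      "n_clusters": {
        "title": "N Clusters",
        "type": "integer"
      },
      "resolution": {
        "title": "Resolution",
        "type": "number"
      },
      "reactor_entropy": {
        "title": "Reactor Entropy",
        "type": "number"
      },
      "reactor_counts": {
        "additionalProperties": {
          "type": "integer"
        },
        "title": "Reactor Counts",
        "type": "object"
      },
      "top_cluster_reactor_fraction": {
        "title": "Top Cluster Reactor Fraction",
        "type": "number"
      },
      "cluster_permutation_p": {
        "title": "Cluster Permutation P",
        "type": "number"
      },
      "n_kw_significant": {
        "title": "N Kw Significant",
        "type": "integer"
      }
    },
    "required": [
      "config",
      "input_hashes",
      "n_samples",
      "n_taxa",
      "n_groups",
      "delta",
      "alr_reference",
      "alr_dim",
      "cv_auroc",
      "pooled_auroc",
      "empirical_p",
      "n_signature_features",
      "signature_features",
      "permanova",
      "permdisp",
      "n_pairwise_comparisons",
      "n_nonsignificant_pairs",
      "n_clusters",
      "resolution",
      "reactor_entropy",
      "reactor_counts",
      "top_cluster_reactor_fraction",
      "cluster_permutation_p",
      "n_kw_significant"
    ],
    "title": "PerturbationReport",
    "type": "object"
  }
}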