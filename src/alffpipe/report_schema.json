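{
  "type": "object",
  "required": ["config", "qc", "counts", "selection", "weights", "metrics",
               "roc_points", "permutation", "behavior_stats", "brain_behavior"],
  "properties": {
    "config": {"type": "object"},
    "qc": {
      "type": "object",
      "required": ["retained_subjects", "n_retained", "excluded"],
      "properties": {
        "retained_subjects": {"type": "array", "items": {"type": "integer"}},
        "n_retained": {"type": "integer"},
        "excluded": {"type": "array", "items": {"type": "object"}}
      }
    },
    "counts": {
      "type": "object",
      "required": ["n_scans", "n_regions", "n_stage1", "n_final"]
    },
    "selection": {
      "type": "object",
      "required": ["mode", "stage1_regions", "final_regions", "accuracy_trace",
                   "removed_per_round"],
      "properties": {
        "mode": {"type": "string"},
        "stage1_regions": {"type": "array", "items": {"type": "integer"}},
        "final_regions": {"type": "array", "items": {"type": "integer"}},
        "accuracy_trace": {"type": "array", "items": {"type": "number"}}
      }
    },
    "weights": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["region", "weight"],
        "properties": {
          "region": {"type": "integer"},
          "weight": {"type": "number"}
        }
      }
    },
    "metrics": {
      "type": "object",
      "required": ["tp", "fn", "tn", "fp", "accuracy", "sensitivity",
                   "specificity", "auc"],
      "properties": {
        "tp": {"type": "integer"},
        "fn": {"type": "integer"},
        "tn": {"type": "integer"},
        "fp": {"type": "integer"},
        "accuracy": {"type": "number"},
        "sensitivity": {"type": "number"},
        "specificity": {"type": "number"},
        "auc": {"type": "number"}
      }
    },
    "roc_points": {"type": "array", "items": {"type": "array"}},
    "permutation": {
      "type": "object",
      "required": ["observed_accuracy", "p_raw", "p_add_one", "B", "seed"],
      "properties": {
        "observed_accuracy": {"type": "number"},
        "p_raw": {"type": "number"},
        "p_add_one": {"type": "number"},
        "B": {"type": "integer"},
        "seed": {"type": "integer"}
      }
    },
    "behavior_stats": {"type": "array", "items": {"type": "object"}},
    "brain_behavior": {"type": "array", "items": {"type": "object"}},
    "truth": {"type": "object"}
  }
}
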