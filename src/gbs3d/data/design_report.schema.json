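{
  "type": "object",
  "required": ["config", "prediction", "budget", "pair_proportions"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["enzymes", "rare_set", "frequent_cutter", "size_window", "seed"],
      "properties": {
        "enzymes": {"type": "array", "items": {"type": "string"}},
        "rare_set": {"type": "array", "items": {"type": "string"}},
        "frequent_cutter": {"type": "string"},
        "size_window": {"type": "array", "items": {"type": "integer"}},
        "adapter_extension": {"type": "integer"},
        "partial_block_probability": {"type": "number"},
        "seed": {"type": "integer"}
      }
    },
    "digest": {
      "type": "object",
      "required": ["cut_sites_total", "fragment_count"],
      "properties": {
        "cut_sites_total": {"type": "integer"},
        "cut_sites_per_enzyme": {"type": "object"},
        "fragment_count": {"type": "integer"},
        "mean_fragment_length": {"type": "number"}
      }
    },
    "prediction": {
      "type": "object",
      "required": ["fragment_count", "captured_bases", "genome_length", "coverage_fraction"],
      "properties": {
        "fragment_count": {"type": "integer"},
        "captured_bases": {"type": "integer"},
        "genome_length": {"type": "integer"},
        "coverage_fraction": {"type": "number"},
        "pair_counts": {"type": "object"}
      }
    },
    "budget": {
      "type": "object",
      "required": ["reads_per_sample", "fragment_count", "expected_depth", "dropout_probability", "min_depth", "p_below_min_depth"],
      "properties": {
        "reads_per_sample": {"type": "integer"},
        "fragment_count": {"type": "integer"},
        "expected_depth": {"type": "number"},
        "dropout_probability": {"type": "number"},
        "min_depth": {"type": "integer"},
        "p_below_min_depth": {"type": "number"},
        "multiplex_capacity": {"type": ["integer", "null"]}
      }
    },
    "pair_proportions": {"type": "object"}
  }
}
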