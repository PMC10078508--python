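{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "mitochar characterization report",
  "type": "object",
  "required": ["record_id", "config", "features", "layout", "skipped"],
  "properties": {
    "record_id": {"type": "string"},
    "config": {"type": "object"},
    "skipped": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["stage", "reason"],
        "properties": {
          "stage": {"type": "string"},
          "reason": {"type": "string"}
        }
      }
    },
    "features": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "category", "strand", "start", "stop", "size_bp"],
        "properties": {
          "name": {"type": "string"},
          "category": {"enum": ["PCG", "tRNA", "rRNA", "control"]},
          "strand": {"enum": ["J", "N"]},
          "start": {"type": "integer", "minimum": 1},
          "stop": {"type": "integer", "minimum": 1},
          "size_bp": {"type": "integer", "minimum": 1},
          "intergenic_bp": {"type": ["integer", "null"]}
        }
      }
    },
    "layout": {
      "type": "object",
      "required": [
        "genome_length", "spacer_count", "overlap_count", "strand_tallies",
        "j_gene_count", "conservation_residual"
      ]
    },
    "composition": {"type": "array"},
    "codon_usage": {
      "type": "object",
      "required": ["total_codons", "genetic_code", "codons", "amino_acid_pct"]
    },
    "repeats": {"type": "array"},
    "divergence": {"type": "array"}
  }
}
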