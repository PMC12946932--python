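{
  "type": "object",
  "required": ["checklist", "assessment", "snomed", "explanation", "metadata"],
  "properties": {
    "checklist": {
      "type": "object",
      "required": ["answers", "confidences", "cues"],
      "properties": {
        "answers": {"type": "object"},
        "confidences": {"type": "object"},
        "cues": {"type": "object"}
      }
    },
    "assessment": {
      "type": "object",
      "required": ["item_scores", "total_score", "band", "diagnosis_label", "provenance"],
      "properties": {
        "item_scores": {"type": "object"},
        "total_score": {"type": "integer"},
        "band": {
          "type": "string",
          "enum": ["minimal", "mild", "moderate", "moderately severe", "severe"]
        },
        "diagnosis_label": {"type": "string"},
        "provenance": {"type": "object"}
      }
    },
    "snomed": {"type": "object"},
    "explanation": {
      "type": "object",
      "required": ["per_item", "narrative", "highlighted_terms"],
      "properties": {
        "per_item": {"type": "object"},
        "narrative": {"type": "string"},
        "highlighted_terms": {"type": "array"}
      }
    },
    "metrics": {"type": "object"},
    "metadata": {
      "type": "object",
      "required": ["config_hash", "seed", "version"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "version": {"type": "string"}
      }
    }
  }
}
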