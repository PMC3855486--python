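{
  "type": "object",
  "required": ["records"],
  "properties": {
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "length", "architecture", "functionality", "lineage", "confidence", "blocks"],
        "properties": {
          "id": {"type": "string"},
          "length": {"type": "integer"},
          "architecture": {"type": "string"},
          "extension_length": {"type": ["integer", "null"]},
          "functionality": {"type": "string"},
          "fired_signatures": {"type": "array", "items": {"type": "string"}},
          "checks": {"type": "object"},
          "lineage": {"type": "string"},
          "confidence": {"type": "number"},
          "lineage_scores": {"type": "object"},
          "taxonomy_hint_used": {"type": "boolean"},
          "blocks": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["block", "matched_as", "start", "end", "score"],
              "properties": {
                "block": {"type": "string"},
                "matched_as": {"type": "string"},
                "start": {"type": "integer"},
                "end": {"type": "integer"},
                "start_1based": {"type": "integer"},
                "score": {"type": "number"}
              }
            }
          }
        }
      }
    }
  }
}
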