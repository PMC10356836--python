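{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "thermodiv run summary",
  "type": "object",
  "required": ["config", "seeds", "classification", "stages"],
  "properties": {
    "config": {"type": "object"},
    "seeds": {"type": "object"},
    "classification": {
      "type": "object",
      "required": ["sensitive_classes", "resistant_classes", "n_sensitive",
                   "n_resistant", "n_other"],
      "properties": {
        "sensitive_classes": {"type": "array", "items": {"type": "integer"}},
        "resistant_classes": {"type": "array", "items": {"type": "integer"}},
        "n_sensitive": {"type": "integer"},
        "n_resistant": {"type": "integer"},
        "n_other": {"type": "integer"}
      }
    },
    "diversity": {"type": "object"},
    "ncm": {"type": "object"},
    "bisse": {"type": "object"},
    "mte": {"type": "object"},
    "stages": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["status"],
        "properties": {
          "status": {"enum": ["ok", "skipped", "failed"]},
          "reason": {"type": "string"}
        }
      }
    }
  }
}
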