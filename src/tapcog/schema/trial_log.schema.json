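{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/tapcog/trial_log.schema.json",
  "title": "Memory-test trial log",
  "description": "One object per trial: ordered tap events grouped into attempts for one test stage. Timestamps are integer milliseconds from trial start.",
  "type": "object",
  "required": ["subject_id", "stage", "session_time", "attempts"],
  "properties": {
    "schema_version": {"type": "string"},
    "subject_id": {"type": "string"},
    "stage": {
      "enum": ["verbal_immediate", "verbal_delayed", "spatial_static", "spatial_dynamic"]
    },
    "session_time": {"type": "string", "format": "date-time"},
    "attempts": {
      "type": "array",
      "items": {
        "oneOf": [
          {
            "type": "object",
            "description": "Spatial attempt",
            "required": ["level", "pattern", "passed", "events"],
            "properties": {
              "level": {"type": "integer", "minimum": 4, "maximum": 8},
              "pattern": {
                "type": "array",
                "items": {"type": "integer", "minimum": 0, "maximum": 15}
              },
              "passed": {"type": "boolean"},
              "events": {"type": "array", "items": {"$ref": "#/$defs/event"}}
            }
          },
          {
            "type": "object",
            "description": "Verbal attempt",
            "required": ["pairs"],
            "properties": {
              "pairs": {
                "type": "array",
                "minItems": 10,
                "maxItems": 10,
                "items": {
                  "type": "object",
                  "required": ["cue", "options", "chosen", "event"],
                  "properties": {
                    "cue": {"type": "string"},
                    "options": {
                      "type": "array",
                      "minItems": 4,
                      "maxItems": 4,
                      "items": {"type": "string"}
                    },
                    "chosen": {"type": "string"},
                    "event": {"$ref": "#/$defs/event"}
                  }
                }
              }
            }
          }
        ]
      }
    }
  },
  "$defs": {
    "event": {
      "type": "object",
      "required": ["t", "action", "target", "correct"],
      "properties": {
        "t": {"type": "integer", "minimum": 0},
        "action": {"enum": ["select", "deselect"]},
        "target": {"type": "integer", "minimum": 0, "maximum": 15},
        "correct": {"type": "boolean"}
      }
    }
  }
}
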