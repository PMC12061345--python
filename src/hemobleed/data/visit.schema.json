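{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "PatientVisit",
  "description": "One hospitalization, serialized as one JSON object per JSONL line.",
  "type": "object",
  "required": ["visit_id", "age", "sex", "surgery_time", "notes"],
  "properties": {
    "visit_id": {"type": "string"},
    "age": {"type": "integer", "minimum": 18},
    "sex": {"enum": ["female", "male"]},
    "surgery_time": {"type": "string", "format": "date-time"},
    "label": {"enum": ["major_bleeding_present", "major_bleeding_absent", null]},
    "notes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["note_id", "visit_id", "note_type", "timestamp", "text"],
        "properties": {
          "note_id": {"type": "string"},
          "visit_id": {"type": "string"},
          "note_type": {"enum": ["admission", "progress", "operative", "transfusion", "discharge"]},
          "timestamp": {"type": "string", "format": "date-time"},
          "text": {"type": "string", "minLength": 1}
        }
      }
    },
    "hb_series": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["timestamp", "value", "unit"],
        "properties": {
          "timestamp": {"type": "string", "format": "date-time"},
          "value": {"type": "number", "exclusiveMinimum": 0},
          "unit": {"enum": ["g_per_L", "g_per_dL"]}
        }
      }
    },
    "transfusions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["timestamp", "product", "quantity", "unit"],
        "properties": {
          "timestamp": {"type": "string", "format": "date-time"},
          "product": {"enum": ["rbc_concentrate", "whole_blood", "other"]},
          "quantity": {"type": "number", "exclusiveMinimum": 0},
          "unit": {"enum": ["U", "mL"]}
        }
      }
    }
  }
}
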