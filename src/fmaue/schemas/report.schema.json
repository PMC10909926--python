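{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "fmaue assessment report",
 "type": "object",
 "required": ["schema_version", "subject_id", "item_scores", "total", "severity"],
 "properties": {
  "schema_version": {"const": 1},
  "subject_id": {"type": "string"},
  "item_scores": {
   "type": "object",
   "additionalProperties": {"type": "integer", "minimum": 0, "maximum": 2}
  },
  "sub_scores": {
   "type": "object",
   "additionalProperties": {"type": "array", "items": {"type": "integer", "minimum": 0, "maximum": 2}}
  },
  "total": {"type": "integer", "minimum": 0, "maximum": 60},
  "severity": {"enum": ["severe", "moderate", "mild"]},
  "features": {
   "type": "object",
   "additionalProperties": {
    "type": "array",
    "items": {"type": "object", "additionalProperties": {"type": "number"}}
   }
  },
  "diagnostics": {"type": "array", "items": {"type": "string"}}
 }
}
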