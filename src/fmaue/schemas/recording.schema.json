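{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "fmaue recording",
 "description": "Paired affected/healthy motion clips (positions in metres, times in seconds) and 16x16 force frames (newtons) for one assessment session.",
 "type": "object",
 "required": ["schema_version", "subject_id", "affected_side", "clips"],
 "properties": {
  "schema_version": {"const": 1},
  "subject_id": {"type": "string"},
  "affected_side": {"enum": ["left", "right"]},
  "mirrored": {"type": "boolean"},
  "clips": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["motion_id", "side", "fs", "body"],
    "properties": {
     "motion_id": {"pattern": "^M([1-9]|1[0-9]|2[01])$"},
     "side": {"enum": ["affected", "healthy"]},
     "fs": {"type": "number", "exclusiveMinimum": 24},
     "body": {
      "type": "object",
      "required": ["t", "joints"],
      "properties": {
       "t": {"type": "array", "items": {"type": "number", "minimum": 0}},
       "joints": {
        "type": "object",
        "additionalProperties": {
         "type": "array",
         "items": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3}
        }
       }
      }
     },
     "hand": {
      "type": ["object", "null"],
      "required": ["t", "landmarks"],
      "properties": {
       "t": {"type": "array", "items": {"type": "number", "minimum": 0}},
       "landmarks": {
        "type": "array",
        "items": {
         "type": "array",
         "minItems": 21,
         "maxItems": 21,
         "items": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3}
        }
       }
      }
     }
    }
   }
  },
  "force_frames": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["motion_id", "side", "t", "grid"],
    "properties": {
     "motion_id": {"enum": ["M16", "M17", "M18", "M19", "M20"]},
     "side": {"enum": ["affected", "healthy"]},
     "t": {"type": "number", "minimum": 0},
     "grid": {
      "type": "array",
      "minItems": 16,
      "maxItems": 16,
      "items": {
       "type": "array",
       "minItems": 16,
       "maxItems": 16,
       "items": {"type": "number", "minimum": 0}
      }
     }
    }
   }
  }
 }
}
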