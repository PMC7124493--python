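{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "StudyRecord",
  "description": "One reviewed study's exposure/outcome/control/mediator structure, as a key-value document (YAML, one document per study). The loader in dagsynth.io enforces these constraints.",
  "type": "object",
  "required": ["study_id", "exposures", "outcomes"],
  "additionalProperties": false,
  "properties": {
    "study_id": {"type": "string", "minLength": 1},
    "citation": {"type": "string"},
    "exposures": {
      "type": "array",
      "items": {"$ref": "#/$defs/node_id"},
      "minItems": 1
    },
    "outcomes": {
      "type": "array",
      "items": {"$ref": "#/$defs/node_id"},
      "minItems": 1
    },
    "controls": {"type": "array", "items": {"$ref": "#/$defs/node_id"}},
    "mediators": {
      "type": "array",
      "description": "(tail, head) edges as concluded by the study",
      "items": {
        "type": "array",
        "items": {"$ref": "#/$defs/node_id"},
        "minItems": 2,
        "maxItems": 2
      }
    },
    "instruments": {
      "type": "array",
      "description": "(instrument, target exposure) pairs",
      "items": {
        "type": "array",
        "items": {"$ref": "#/$defs/node_id"},
        "minItems": 2,
        "maxItems": 2
      }
    },
    "labels": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "aliases": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "string"}}
    }
  },
  "$defs": {
    "node_id": {
      "type": "string",
      "pattern": "^[a-z0-9_.]+$",
      "description": "canonical node token: lowercase, no whitespace"
    }
  }
}
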