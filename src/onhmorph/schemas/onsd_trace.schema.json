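{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "OnsdTrace",
  "description": "Optic nerve sheath ultrasound traces in millimetres.",
  "type": "object",
  "required": ["globe_posterior", "axis", "sheath_upper", "sheath_lower"],
  "properties": {
    "globe_posterior": {"$ref": "#/$defs/point"},
    "axis": {"$ref": "#/$defs/polyline"},
    "sheath_upper": {"$ref": "#/$defs/polyline"},
    "sheath_lower": {"$ref": "#/$defs/polyline"}
  },
  "$defs": {
    "point": {"type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}},
    "polyline": {"type": "array", "minItems": 2, "items": {"$ref": "#/$defs/point"}}
  }
}
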