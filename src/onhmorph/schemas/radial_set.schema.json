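{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SegmentedRadialSet",
  "description": "24 radial B-scans with layer polylines and BMO marks; coordinates in micrometres, z anterior-positive.",
  "type": "object",
  "required": ["eye", "axial_sign", "bscans"],
  "properties": {
    "eye": {"enum": ["OD", "OS"]},
    "axial_sign": {"enum": [1, -1]},
    "bscans": {
      "type": "array",
      "minItems": 24,
      "maxItems": 24,
      "items": {
        "type": "object",
        "required": ["index", "angle_deg", "ilm", "bm", "bmo_left", "bmo_right"],
        "properties": {
          "index": {"type": "integer", "minimum": 0, "maximum": 23},
          "angle_deg": {"type": "number"},
          "ilm": {"$ref": "#/$defs/polyline"},
          "bm": {"$ref": "#/$defs/polyline"},
          "alcs": {"$ref": "#/$defs/polyline"},
          "bmo_left": {"$ref": "#/$defs/point"},
          "bmo_right": {"$ref": "#/$defs/point"}
        }
      }
    }
  },
  "$defs": {
    "point": {
      "type": "array",
      "minItems": 2,
      "maxItems": 2,
      "items": {"type": "number"}
    },
    "polyline": {
      "type": "array",
      "minItems": 2,
      "items": {"$ref": "#/$defs/point"}
    }
  }
}
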