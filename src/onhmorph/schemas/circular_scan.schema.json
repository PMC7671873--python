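{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CircularScan",
  "description": "Circumpapillary circular B-scan; theta in degrees (strictly increasing, span >= 359), z arrays in micrometres.",
  "type": "object",
  "required": ["diameter_mm", "theta", "ilm_z", "rnfl_post_z", "bm_z", "choroid_sclera_z", "valid"],
  "properties": {
    "diameter_mm": {"enum": [2.7, 3.5, 4.2, 4.9]},
    "theta": {"type": "array", "items": {"type": "number"}},
    "ilm_z": {"type": "array", "items": {"type": "number"}},
    "rnfl_post_z": {"type": "array", "items": {"type": "number"}},
    "bm_z": {"type": "array", "items": {"type": "number"}},
    "choroid_sclera_z": {"type": "array", "items": {"type": "number"}},
    "valid": {"type": "array", "items": {"type": "boolean"}}
  }
}
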