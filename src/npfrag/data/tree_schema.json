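{
 "$schema": "http://json-schema.org/draft-07/schema#",
 "title": "Fragment tree",
 "type": "object",
 "required": ["precursor", "nodes", "edges"],
 "properties": {
  "precursor": {"type": "string"},
  "nodes": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": ["id", "mz", "formula", "kind"],
    "properties": {
     "id": {"type": "string"},
     "mz": {"type": "number"},
     "formula": {"type": "string"},
     "kind": {"enum": ["precursor", "fragment"]},
     "intensity": {"type": ["number", "null"]}
    }
   }
  },
  "edges": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["source", "target", "loss", "loss_mass"],
    "properties": {
     "source": {"type": "string"},
     "target": {"type": "string"},
     "loss": {"type": "string"},
     "loss_mass": {"type": "number"}
    }
   }
  }
 }
}
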