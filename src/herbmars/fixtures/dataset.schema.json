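{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "herbmars dataset document",
 "description": "Evidence dataset for Herb MaRS marker scoring: plants with labelled indications, per-compound dossiers, and a catalog of regulatory limits. schema_version 1.0.",
 "type": "object",
 "required": ["schema_version", "plants", "compounds"],
 "properties": {
  "schema_version": {"type": "string"},
  "plants": {"type": "array", "items": {"$ref": "#/$defs/plant"}},
  "compounds": {"type": "array", "items": {"$ref": "#/$defs/compound"}},
  "limits": {"type": "array", "items": {"$ref": "#/$defs/limit"}}
 },
 "$defs": {
  "plant": {
   "type": "object",
   "required": ["botanical_name", "part_used"],
   "properties": {
    "botanical_name": {"type": "string", "minLength": 1},
    "family": {"type": "string"},
    "source": {"enum": ["wild", "cultivated", "both"]},
    "part_used": {"type": "array", "items": {"type": "string"}, "minItems": 1},
    "dosage_forms": {"type": "array", "items": {"type": "string"}},
    "indications": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["condition"],
      "properties": {
       "condition": {"type": "string"},
       "symptoms": {"type": "array", "items": {"type": "string"}, "uniqueItems": true}
      }
     }
    }
   }
  },
  "concentration": {
   "type": "object",
   "required": ["raw_text", "determined"],
   "properties": {
    "raw_text": {"type": "string"},
    "determined": {"type": "boolean"},
    "low": {"type": ["number", "null"], "minimum": 0},
    "high": {"type": ["number", "null"], "minimum": 0},
    "unit": {"enum": ["percent_w_w", "mg_per_g", "ppm", null]},
    "basis": {"type": "string"}
   }
  },
  "standard": {
   "type": "object",
   "required": ["vendor", "pack_value", "pack_unit", "price_eur"],
   "properties": {
    "vendor": {"type": "string"},
    "grade": {"type": "string"},
    "pack_value": {"type": "number", "exclusiveMinimum": 0},
    "pack_unit": {"enum": ["mg", "mL", "g"]},
    "price_eur": {"type": "number", "exclusiveMinimum": 0}
   }
  },
  "method": {
   "type": "object",
   "required": ["technique"],
   "properties": {
    "technique": {"type": "string", "minLength": 1},
    "matrix": {"type": "string"},
    "citation": {"type": "string"}
   }
  },
  "limit": {
   "type": "object",
   "required": ["authority", "analyte", "limit_ppm"],
   "properties": {
    "authority": {"type": "string"},
    "analyte": {"type": "string"},
    "limit_ppm": {"type": "number", "minimum": 0},
    "direction": {"const": "maximum"}
   }
  },
  "components": {
   "type": "object",
   "required": ["a", "b", "c", "d", "e", "f"],
   "properties": {
    "a": {"type": "integer", "minimum": 0, "maximum": 1},
    "b": {"type": "integer", "minimum": 0, "maximum": 3},
    "c": {"type": "integer", "minimum": 0, "maximum": 1},
    "d": {"type": "integer", "minimum": 0, "maximum": 1},
    "e": {"type": "integer", "minimum": 0, "maximum": 1},
    "f": {"type": "integer", "minimum": 0, "maximum": 1}
   }
  },
  "compound": {
   "type": "object",
   "required": ["compound_id", "name", "plant", "concentration"],
   "properties": {
    "compound_id": {"type": "string", "minLength": 1},
    "name": {"type": "string", "minLength": 1},
    "plant": {"type": "string", "description": "botanical_name of a plant in this document"},
    "documented_constituent": {"type": "boolean"},
    "activities": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["activity_name"],
      "properties": {
       "activity_name": {"type": "string"},
       "symptoms_addressed": {"type": "array", "items": {"type": "string"}},
       "relevant_to_indication": {"type": "boolean"},
       "mechanism": {"type": "string"},
       "citations": {"type": "array", "items": {"type": "string"}}
      }
     }
    },
    "concentration": {"$ref": "#/$defs/concentration"},
    "standards": {"type": "array", "items": {"$ref": "#/$defs/standard"}},
    "methods": {"type": "array", "items": {"$ref": "#/$defs/method"}},
    "toxic": {"type": "boolean"},
    "negative_marker_limits": {"type": "array", "items": {"$ref": "#/$defs/limit"}},
    "recorded_components": {"oneOf": [{"$ref": "#/$defs/components"}, {"type": "null"}]},
    "recorded_total": {"type": ["integer", "null"], "minimum": 0, "maximum": 8}
   }
  }
 }
}
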