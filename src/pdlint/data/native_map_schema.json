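{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pdlint native map document",
  "type": "object",
  "required": ["format_version", "map"],
  "properties": {
    "format_version": {"type": "string"},
    "map": {
      "type": "object",
      "required": ["map_name", "compartments", "pools", "complexes", "processes"],
      "properties": {
        "map_name": {"type": "string", "minLength": 1},
        "provenance": {"type": "string"},
        "compartments": {"type": "array", "items": {"type": "string"}},
        "pools": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["pool_id", "label", "protein_key", "uniprot_ids", "is_generic", "members", "state", "compartment"],
            "properties": {
              "pool_id": {"type": "string", "minLength": 1},
              "label": {"type": "string"},
              "protein_key": {"type": "string", "minLength": 1},
              "uniprot_ids": {"type": "array", "items": {"type": "string"}},
              "is_generic": {"type": "boolean"},
              "members": {"type": "array", "items": {"type": "string"}},
              "state": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["site", "value"],
                  "properties": {
                    "site": {"type": "string", "minLength": 1},
                    "value": {"type": "string"}
                  }
                }
              },
              "compartment": {"type": "string"}
            }
          }
        },
        "complexes": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["pool_id", "components"],
            "properties": {
              "pool_id": {"type": "string", "minLength": 1},
              "components": {"type": "array", "items": {"type": "string"}, "minItems": 1},
              "compartment": {"type": "string"}
            }
          }
        },
        "processes": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["process_id", "kind", "reactants", "products", "modulators"],
            "properties": {
              "process_id": {"type": "string", "minLength": 1},
              "kind": {"enum": ["state_transition", "association", "dissociation", "generic_process"]},
              "reactants": {"type": "array", "items": {"type": "string"}},
              "products": {"type": "array", "items": {"type": "string"}},
              "modulators": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["pool", "class"],
                  "properties": {
                    "pool": {"type": "string"},
                    "class": {"enum": ["catalysis", "stimulation", "unknown"]}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
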