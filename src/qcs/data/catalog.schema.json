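{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "qcs-catalog-schema-v1",
  "title": "QCS catalog document, schema version 1",
  "description": "Rule base for multimorbidity screening: comorbid conditions with clinical-code mappings, plus qualifying sets of 1-3 condition ids. Codes may be written dotted or undotted; they are normalized (uppercase, no periods/whitespace) on load.",
  "type": "object",
  "required": ["version", "conditions", "sets"],
  "properties": {
    "version": {"type": "string"},
    "non_clinical": {
      "type": "boolean",
      "default": false,
      "description": "True for demonstration catalogs whose rules are NOT clinically derived; classification of real claims requires explicit opt-in."
    },
    "conditions": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "organ_system"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "display_name": {"type": "string"},
          "organ_system": {"type": "string", "minLength": 1},
          "clinical_definition": {"type": "string"},
          "included_diagnoses": {"type": "array", "items": {"type": "string"}},
          "excluded_diagnoses": {"type": "array", "items": {"type": "string"}},
          "codes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["system", "code"],
              "properties": {
                "system": {"enum": ["ICD9CM", "ICD10CM", "CPT", "HCPCS"]},
                "code": {"type": "string", "minLength": 1},
                "match": {"enum": ["exact", "prefix"], "default": "exact"}
              }
            }
          }
        }
      }
    },
    "sets": {
      "type": "array",
      "items": {
        "type": "array",
        "minItems": 1,
        "maxItems": 3,
        "uniqueItems": true,
        "items": {"type": "string"}
      }
    }
  }
}
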