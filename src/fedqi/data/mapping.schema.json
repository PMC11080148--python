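{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://w3id.org/fedqi/schema/ontology-mapping",
  "title": "Column -> RDF ontology mapping",
  "type": "object",
  "required": ["base_namespace", "columns"],
  "properties": {
    "base_namespace": {"type": "string", "format": "iri"},
    "columns": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["predicate_iri", "datatype"],
        "additionalProperties": false,
        "properties": {
          "predicate_iri": {"type": "string", "format": "iri"},
          "datatype": {"enum": ["date", "boolean", "integer", "decimal", "coded_text"]},
          "concept_code": {"type": "string"},
          "value_codes": {
            "type": "object",
            "additionalProperties": {"type": "string"}
          }
        }
      }
    }
  }
}
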