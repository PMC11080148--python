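{
  "_comment": "Default column -> RDF mapping for the colorectal-audit variable set. Terminology codes are placeholder-but-plausible SNOMED CT identifiers and are CONFIGURATION: replace them with the codes your governance approves. Predicates live in the project namespace and are linked to their code via an annotation triple.",
  "base_namespace": "https://w3id.org/fedqi/",
  "columns": {
    "hospital_id": {
      "predicate_iri": "https://w3id.org/fedqi/hospitalId",
      "datatype": "coded_text",
      "concept_code": "257622000"
    },
    "tumor_localization": {
      "predicate_iri": "https://w3id.org/fedqi/tumorLocalization",
      "datatype": "coded_text",
      "concept_code": "399687005",
      "value_codes": {
        "colon": "71854001",
        "rectum": "34402009"
      }
    },
    "referred": {
      "predicate_iri": "https://w3id.org/fedqi/referred",
      "datatype": "boolean",
      "concept_code": "3457005"
    },
    "date_of_diagnosis": {
      "predicate_iri": "https://w3id.org/fedqi/dateOfDiagnosis",
      "datatype": "date",
      "concept_code": "432213005"
    },
    "date_neoadjuvant_start": {
      "predicate_iri": "https://w3id.org/fedqi/dateNeoadjuvantStart",
      "datatype": "date",
      "concept_code": "703423002"
    },
    "date_of_surgery": {
      "predicate_iri": "https://w3id.org/fedqi/dateOfSurgery",
      "datatype": "date",
      "concept_code": "442137000"
    },
    "resection_type": {
      "predicate_iri": "https://w3id.org/fedqi/resectionType",
      "datatype": "coded_text",
      "concept_code": "128304005",
      "value_codes": {
        "low_anterior_resection": "314592006",
        "abdominoperineal_resection": "265414003",
        "sigmoid_resection": "88312006",
        "right_hemicolectomy": "359571009"
      }
    },
    "age": {
      "predicate_iri": "https://w3id.org/fedqi/age",
      "datatype": "integer",
      "concept_code": "424144002"
    },
    "bmi": {
      "predicate_iri": "https://w3id.org/fedqi/bodyMassIndex",
      "datatype": "decimal",
      "concept_code": "60621009"
    },
    "charlson_score": {
      "predicate_iri": "https://w3id.org/fedqi/charlsonComorbidityScore",
      "datatype": "integer",
      "concept_code": "762713009"
    },
    "asa_class": {
      "predicate_iri": "https://w3id.org/fedqi/asaClass",
      "datatype": "integer",
      "concept_code": "302132005"
    },
    "preop_tumor_complication": {
      "predicate_iri": "https://w3id.org/fedqi/preoperativeTumorComplication",
      "datatype": "boolean",
      "concept_code": "116223007"
    },
    "postop_complication": {
      "predicate_iri": "https://w3id.org/fedqi/postoperativeComplication",
      "datatype": "boolean",
      "concept_code": "385486001"
    }
  }
}
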