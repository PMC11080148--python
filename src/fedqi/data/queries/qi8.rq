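# Cohort retrieval for the postoperative-complication indicator.
# Case-mix variables (age, BMI, Charlson, ASA, preoperative complications)
# travel with the cohort but are not used in adjustment (crude rate).
PREFIX fq: <https://w3id.org/fedqi/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?patient ?localization ?referred ?postop_complication ?age ?bmi ?charlson_score ?asa_class ?preop_tumor_complication
WHERE {
  ?patient a fq:Patient .
  ?patient fq:tumorLocalization ?loc .
  ?loc rdfs:label ?localization .
  ?patient fq:referred ?referred .
  ?patient fq:postoperativeComplication ?postop_complication .
  ?patient fq:age ?age .
  ?patient fq:bodyMassIndex ?bmi .
  ?patient fq:charlsonComorbidityScore ?charlson_score .
  ?patient fq:asaClass ?asa_class .
  ?patient fq:preoperativeTumorComplication ?preop_tumor_complication .
}
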