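# Cohort retrieval for the short-waiting-time indicator.
# Returns one row per patient with the localization label, referral flag,
# and the three therapy-timing dates (neoadjuvant start is optional).
PREFIX fq: <https://w3id.org/fedqi/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?patient ?localization ?referred ?date_of_diagnosis ?date_neoadjuvant_start ?date_of_surgery
WHERE {
  ?patient a fq:Patient .
  ?patient fq:tumorLocalization ?loc .
  ?loc rdfs:label ?localization .
  ?patient fq:referred ?referred .
  ?patient fq:dateOfDiagnosis ?date_of_diagnosis .
  ?patient fq:dateOfSurgery ?date_of_surgery .
  OPTIONAL { ?patient fq:dateNeoadjuvantStart ?date_neoadjuvant_start . }
}
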