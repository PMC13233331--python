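# Exemplar three-level diagnostic label hierarchy for peripheral-blood
# cytomorphology triage: raw laboratory labels -> detailed classes -> 8
# coarse classes.  Users may supply their own file with the same schema;
# see hemomil.hierarchy.load_hierarchy for validation rules.
coarse_classes:
  - acute leukemia
  - MDS
  - MDS/MPN
  - MPN
  - lymphoma
  - plasma cell neoplasm
  - reactive changes
  - healthy

malignant:
  acute leukemia: true
  MDS: true
  MDS/MPN: true
  MPN: true
  lymphoma: true
  plasma cell neoplasm: true
  reactive changes: false
  healthy: false

detailed_to_coarse:
  AML: acute leukemia
  ALL: acute leukemia
  MDS: MDS
  MDS/MPN: MDS/MPN
  ET: MPN
  PV: MPN
  CML: MPN
  other MPN: MPN
  CLL: lymphoma
  lymphoma (excluding CLL): lymphoma
  multiple myeloma: plasma cell neoplasm
  MGUS: plasma cell neoplasm
  reactive changes: reactive changes
  healthy: healthy

raw_to_detailed:
  AML: AML
  APL: AML
  AML with maturation: AML
  acute myelomonocytic leukemia: AML
  ALL: ALL
  B-ALL: ALL
  T-ALL: ALL
  MDS: MDS
  MDS with low blasts: MDS
  MDS with increased blasts: MDS
  MDS/MPN: MDS/MPN
  CMML: MDS/MPN
  atypical CML: MDS/MPN
  ET: ET
  PV: PV
  CML: CML
  primary myelofibrosis: other MPN
  MPN unclassifiable: other MPN
  CLL: CLL
  hairy cell leukemia: lymphoma (excluding CLL)
  mantle cell lymphoma: lymphoma (excluding CLL)
  marginal zone lymphoma: lymphoma (excluding CLL)
  follicular lymphoma: lymphoma (excluding CLL)
  multiple myeloma: multiple myeloma
  MGUS: MGUS
  reactive changes: reactive changes
  reactive lymphocytosis: reactive changes
  infection-associated changes: reactive changes
  healthy: healthy
  stem cell donor: healthy
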