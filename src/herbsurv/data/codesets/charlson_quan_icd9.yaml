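# Charlson comorbidity categories, Quan ICD-9-CM enumeration, original
# Charlson weights.  V-codes from Quan's enumeration (V43.4, V42.0, V42.7,
# V45.1, V56.x) are omitted: the code-pattern grammar used throughout this
# package is numeric rubrics only, and the affected status codes are
# negligible in diagnosis claims.  Dotted ranges in the published table are
# expanded to explicit dotted prefixes.
name: charlson_quan_icd9
categories:
  myocardial_infarction:
    weight: 1
    entries: ["410", "412"]
  congestive_heart_failure:
    weight: 1
    entries: ["398.91", "402.01", "402.11", "402.91", "404.01", "404.03",
              "404.11", "404.13", "404.91", "404.93",
              "425.4", "425.5", "425.6", "425.7", "425.8", "425.9", "428"]
  peripheral_vascular:
    weight: 1
    entries: ["093.0", "437.3", "440", "441",
              "443.1", "443.2", "443.3", "443.4", "443.5", "443.6", "443.7",
              "443.8", "443.9", "447.1", "557.1", "557.9"]
  cerebrovascular:
    weight: 1
    entries: ["362.34", "430-438"]
  dementia:
    weight: 1
    entries: ["290", "294.1", "331.2"]
  chronic_pulmonary:
    weight: 1
    entries: ["416.8", "416.9", "490-505", "506.4", "508.1", "508.8"]
  rheumatic:
    weight: 1
    entries: ["446.5", "710.0", "710.1", "710.2", "710.3", "710.4",
              "714.0", "714.1", "714.2", "714.8", "725"]
  peptic_ulcer:
    weight: 1
    entries: ["531-534"]
  mild_liver:
    weight: 1
    entries: ["070.22", "070.23", "070.32", "070.33", "070.44", "070.54",
              "070.6", "070.9", "570", "571",
              "573.3", "573.4", "573.8", "573.9"]
  diabetes:
    weight: 1
    entries: ["250.0", "250.1", "250.2", "250.3", "250.8", "250.9"]
  diabetes_complicated:
    weight: 2
    entries: ["250.4", "250.5", "250.6", "250.7"]
  hemiplegia:
    weight: 2
    entries: ["334.1", "342", "343",
              "344.0", "344.1", "344.2", "344.3", "344.4", "344.5", "344.6",
              "344.9"]
  renal:
    weight: 2
    entries: ["403.01", "403.11", "403.91", "404.02", "404.12", "404.92",
              "582", "583.0", "583.1", "583.2", "583.3", "583.4", "583.5",
              "583.6", "583.7", "585", "586", "588.0"]
  malignancy:
    weight: 2
    entries: ["140-172", "174-195", "200-208", "238.6"]
  moderate_severe_liver:
    weight: 3
    entries: ["456.0", "456.1", "456.2",
              "572.2", "572.3", "572.4", "572.5", "572.6", "572.7", "572.8"]
  metastatic:
    weight: 6
    entries: ["196-199"]
  aids:
    weight: 6
    entries: ["042-044"]
# Hierarchy: when both members of a pair are present only the severer one
# is scored and counted.
hierarchy:
  - ["diabetes", "diabetes_complicated"]
  - ["mild_liver", "moderate_severe_liver"]
  - ["malignancy", "metastatic"]
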