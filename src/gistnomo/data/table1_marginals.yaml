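# Whole-population category counts for a 5463-patient gastric-GIST cohort
# (SEER 2000-2020 era structure). Marginal probabilities are derived as
# count / total at load time so they sum to 1 exactly.
total: 5463
age:
  median: 64.0
  q25: 54.0
  q75: 73.0
  lower: 20.0
  upper: 95.0
variables:
  Sex:
    Male: 2650
    Female: 2813
  Race:
    White: 3409
    Black: 1234
    Others: 820
  Marital_status:
    Married: 3321
    Single: 2142
  Tumor_location:
    Antrum or Pylorus: 622
    Body: 2971
    Cardia or Fundus: 1870
  Tumor_grade:
    Well/moderately differentiated: 3939
    Poorly differentiated/undifferentiated: 1524
  Tumor_size:
    "<=2 cm": 697
    "2-5 cm": 1782
    "5-10 cm": 1677
    ">=10 cm": 1307
  AJCC_stage:
    I: 3031
    II: 734
    III: 676
    IV: 1022
  Mitotic_rate:
    "<=5/5 HPF": 4081
    ">5/5 HPF": 1382
  Surgery:
    Local excision: 608
    Radical excision: 4010
    No surgery: 845
  Regional_nodes_examined:
    "0": 4177
    "1-4": 675
    ">4": 611
  Chemotherapy:
    "Yes": 2175
    No/Unknown: 3288
references:
  Sex: Female
  Race: White
  Marital_status: Married
  Tumor_location: Antrum or Pylorus
  Tumor_grade: Well/moderately differentiated
  Tumor_size: "<=2 cm"
  AJCC_stage: I
  Mitotic_rate: "<=5/5 HPF"
  Surgery: Local excision
  Regional_nodes_examined: "0"
  Chemotherapy: No/Unknown
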