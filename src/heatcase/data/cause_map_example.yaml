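# Example cause map in clinical-classification style, at mixed granularity:
# 3-4 digit ICD-9-CM patterns (dots removed) match as prefixes, 5-digit
# patterns exactly.  Illustrative grouping, not a certified crosswalk;
# supply your own map for production analyses.
cause_map:
  alcohol_related: ["291", "303", "3050"]
  substance_related: ["292", "304", "3052", "3053", "3054", "3055", "3056",
                      "3057", "3058", "3059"]
  cannabis: ["3043", "3052"]
  cocaine: ["3042", "3056"]
  opioids: ["3040", "3047", "3055"]
  sedatives: ["3041", "3054"]
city_units: []
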