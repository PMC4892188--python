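{
  "description": "Headline bookkeeping counts from a published 127-patient 22q11.2 deletion targeted-resequencing cohort; used for worked-example arithmetic (percentages, class totals), not as computed results of this package.",
  "initial_hemizygous_positions": 18153,
  "post_filter_positions": 11913,
  "annotated_initial": 10493,
  "annotated_post_filter": 9990,
  "coding_positions": 199,
  "synonymous": 88,
  "non_synonymous": 95,
  "stop_gain": 3,
  "frameshift_insertion": 2,
  "rare_non_synonymous": 63,
  "rare_stop_gain": 2,
  "rare_frameshift_insertion": 1,
  "deletion_class_counts": {
    "AB": 8,
    "AC": 2,
    "AD": 111,
    "BD": 4,
    "A+B": 1,
    "AC-": 1
  },
  "mean_variants_per_patient_by_class": {
    "AB": 1201,
    "AC": 1317,
    "AD": 1538,
    "BD": 572,
    "AC-": 587,
    "A+B": 835
  },
  "platform_patients": {
    "nimblegen": 72,
    "agilent": 55
  },
  "platform_pct_het_in_hemizygous": {
    "nimblegen": 11.6,
    "agilent": 24.3
  }
}
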