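# Per-trait study exclusions applied before pooling genetic estimates, to
# avoid sample overlap between the cohort analyses and the consortium GWAS
# supplying the look-up estimates. Phenotypic pooling uses the two cohorts
# with individual-level intake data and excludes nothing.
genetic:
  bmi: {"1958bc": overlap_with_consortium, hrs: overlap_with_consortium}
  wc: {"1958bc": overlap_with_consortium, hrs: overlap_with_consortium}
  sbp: {"1958bc": overlap_with_consortium, uk_biobank: overlap_with_consortium}
  dbp: {"1958bc": overlap_with_consortium, uk_biobank: overlap_with_consortium}
  hdl_c: {"1958bc": overlap_with_consortium}
  ldl_c: {"1958bc": overlap_with_consortium}
  total_cholesterol: {"1958bc": overlap_with_consortium}
  triglycerides: {"1958bc": overlap_with_consortium}
  hba1c: {"1958bc": overlap_with_consortium}
phenotypic: {}
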