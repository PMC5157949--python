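# Default primate lineage parameters for the two-category rate model.
#
# These are editable defaults, not fitted quantities.  Branch lengths are
# approximate species-side times since the split from the human lineage,
# rounded from commonly used molecular/fossil divergence estimates
# (great-ape and old-world-monkey splits in the 6-30 Myr range).  Generation
# times are literature-typical pedigree/life-history values; orangutan is the
# outlier with the longest generation time among these primates (estimated in
# females only), which is why enrichment predictions are monotone in
# generation time but not exactly in relatedness.
lineages:
  chimpanzee:
    branch_years: 6.5e6
    generation_years: 24.6
  gorilla:
    branch_years: 9.0e6
    generation_years: 19.3
  orangutan:
    branch_years: 16.0e6
    generation_years: 26.9
  gibbon:
    branch_years: 20.0e6
    generation_years: 10.9
  macaque:
    branch_years: 30.0e6
    generation_years: 10.5
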