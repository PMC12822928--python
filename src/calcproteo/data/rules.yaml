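# Homolog handling for dietary peptide matches.
# exclusions: accessions whose hits are discarded (bacterial "hypothetical
#   protein" entries that carry dairy peptides through genome-sequencing
#   contamination).
# reassignments: accession -> dietary protein name; hits are counted as that
#   protein but contribute no taxon evidence of their own.
exclusions:
  - WP_229715011
reassignments:
  MBO8907834: BLG
# Reporting configuration for taxonomic labels.
ceiling_rank_node: Mammalia
rollup:
  Bos: Bovinae
display_groups:
  Pecora: Pecora and Bovidae
  Bovidae: Pecora and Bovidae
  Bovinae: Bovinae and/or Ovis
  Ovis: Bovinae and/or Ovis
  Bovinae/Ovis: Bovinae and/or Ovis
  Caprinae: Caprinae and Capra
  Capra: Caprinae and Capra
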