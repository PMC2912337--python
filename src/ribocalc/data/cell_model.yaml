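# Default cell model: exponentially growing S. cerevisiae.
cell:
  total_transcripts: 36000        # X, mRNA molecules per cell
  total_ribosomes: 200000         # W, ribosomes per cell
  active_fraction: 0.85           # q, fraction of ribosomes translating
  genome_size: 2.8e7              # nt, genome size used for RNA-mass bookkeeping
  rna_dna_ratio: 50.0             # total RNA mass : DNA mass
  mrna_fraction: 0.05             # fraction of total RNA that is mRNA
  trna_fraction: 0.15             # fraction of total RNA that is tRNA
  mean_trna_length: 74.5          # nt, mean tRNA length
  temperature: 30                 # Celsius; one of 20, 24, 30, 37
  cytoplasm_volume: 4.2e-17       # m^3

# Edge length (m) of one cytoplasmic walker occupation site.  Changing it
# rescales the number of occupation sites (and hence all aa-tRNA arrival
# times) but nothing else.
walker_size: 5.9e-9

# Absolute half-life anchor: gene with an independently measured absolute
# half-life used to calibrate the relative half-life table.  The default,
# HIS3, has measured half-lives of 7 min (24 C) and 11 min (30 C); the
# default anchor is their mean.
anchor_gene: YOR202W
anchor_minutes: 9.0
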