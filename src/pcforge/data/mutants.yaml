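# Hydrogenase-deficient mutant library for M. maripaludis knockout
# simulations. Gene names are annotation symbols; map them to the host
# model's locus tags before use. The GAPOR reaction is forced to zero in
# all mutants and reactivated only in the suppressor strains; its
# reaction id must be substituted for the GAPOR placeholder.
d3h2ase:
  deleted_genes: [frcA, frcG, frcB, fruA, fruG, fruB, hmd]
  forced_zero_reactions: [GAPOR]
d5h2ase:
  deleted_genes: [fruA, frcA, hmd, vhuA, vhuU, vhcA]
  forced_zero_reactions: [GAPOR]
d6h2ase:
  deleted_genes: [fruA, frcA, hmd, vhuA, vhuU, vhcA, ehbN]
  forced_zero_reactions: [GAPOR]
d6h2ase_dcdh:
  deleted_genes: [fruA, frcA, hmd, vhuA, vhuU, vhcA, ehbN, cdh]
  forced_zero_reactions: [GAPOR]
# suppressor strains: GAPOR reactivated (not forced to zero); its
# abundance can additionally be capped to 1% of total protein via
# protein_caps when comparing with promoter-mutation experiments.
d6h2ase_sup:
  deleted_genes: [fruA, frcA, hmd, vhuA, vhuU, vhcA, ehbN]
  forced_zero_reactions: []
d7h2ase_sup:
  deleted_genes: [fruA, frcA, hmd, vhuA, vhuU, vhcA, ehbN, ehaN, ehaO]
  forced_zero_reactions: []
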