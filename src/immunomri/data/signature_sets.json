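{
  "description": "Editable toy immune signature gene sets for synthetic cohorts. Gene identifiers are placeholders, not a commercial panel's content.",
  "shift_constants": {
    "t_cell": 0.0,
    "nk_cell": 0.0,
    "b_cell": 0.0,
    "dendritic_cell": 0.0,
    "cytotoxic": 0.0,
    "cd45": 0.0
  },
  "gene_sets": {
    "t_cell": ["TC01", "TC02", "TC03", "TC04", "TC05", "TC06", "TC07", "TC08"],
    "nk_cell": ["NK01", "NK02", "NK03", "NK04", "NK05", "NK06", "NK07", "NK08"],
    "b_cell": ["BC01", "BC02", "BC03", "BC04", "BC05", "BC06", "BC07", "BC08"],
    "dendritic_cell": ["DC01", "DC02", "DC03", "DC04", "DC05", "DC06", "DC07", "DC08"],
    "cytotoxic": ["CT01", "CT02", "CT03", "CT04", "CT05", "CT06", "CT07", "CT08"],
    "cd45": ["CD45A", "CD45B", "CD45C", "CD45D", "CD45E", "CD45F", "CD45G", "CD45H"]
  }
}
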