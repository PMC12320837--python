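{
  "description": "Salivary co-occurrence cluster memberships (SILVA v132 L6 genus labels) used by the upper-GI microbiota typing scheme: the Prevotella 7-dominated cluster (10 genera) and the Neisseria-dominated cluster (13 genera).",
  "anchors": {
    "Prevotella 7": "Prevotella 7",
    "Neisseria": "Neisseria"
  },
  "clusters": {
    "Prevotella 7": [
      "Prevotella 7",
      "Lachnoanaerobaculum",
      "Megasphaera",
      "Prevotella 6",
      "Actinomyces",
      "Veillonella",
      "Alloscardovia",
      "Atopobium",
      "Saccharimonadaceae",
      "Selenomonas 3"
    ],
    "Neisseria": [
      "Neisseria",
      "Porphyromonas",
      "Bergeyella",
      "Parvimonas",
      "Prevotella 2",
      "SR1 bacterium oral taxon 875",
      "Peptostreptococcus",
      "candidate division SR1 bacterium MGEHA",
      "Capnocytophaga",
      "Johnsonella",
      "Gemella",
      "Lautropia",
      "Peptococcus"
    ]
  }
}
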