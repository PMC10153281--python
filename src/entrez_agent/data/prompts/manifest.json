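{
  "note": "Synthetic placeholder component bodies. They honor the structural markup the engine depends on (bracketed URLs, the '–>' call indicator, 'Answer:' lines) and are meant to be replaced by user-supplied texts; the entities and identifiers in the demonstrations are invented.",
  "components": {
    "instruction": {"file": "instruction.txt", "database": "", "function": ""},
    "dc1": {"file": "dc1_eutils_documentation.txt", "database": "gene,snp,omim", "function": "esearch,efetch,esummary"},
    "dc2": {"file": "dc2_blast_documentation.txt", "database": "nt", "function": "blastn"},
    "dm1": {"file": "dm1_gene_alias.txt", "database": "gene", "function": "esearch->efetch"},
    "dm2": {"file": "dm2_gene_snp.txt", "database": "snp", "function": "esummary"},
    "dm3": {"file": "dm3_gene_disease.txt", "database": "omim", "function": "esearch->esummary"},
    "dm4": {"file": "dm4_alignment.txt", "database": "nt", "function": "blastn"}
  }
}
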