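Question: Which gene is SNP rs100000001 associated with?
[https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esummary.fcgi?db=snp&id=100000001&retmode=json]–>[{"result": {"100000001": {"snp_id": 100000001, "genes": [{"name": "GXB2", "gene_id": "901234"}], "chr": "11"}}}]
Answer: GXB2
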