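Question: What is the official gene symbol of GX-42B?
[https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi?db=gene&retmax=5&retmode=json&sort=relevance&term=GX-42B]–>[{"esearchresult": {"count": "1", "idlist": ["901234"]}}]
[https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=gene&id=901234&retmode=json]–>[901234. GXB2 Official Symbol: GXB2 and Name: GX homolog B2 [Homo sapiens] Other Aliases: GX-42B, GXL2]
Answer: GXB2
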