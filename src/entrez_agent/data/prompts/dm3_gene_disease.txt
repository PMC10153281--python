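Question: What are genes related to Example disease syndrome?
[https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi?db=omim&retmax=20&retmode=json&sort=relevance&term=Example+disease+syndrome]–>[{"esearchresult": {"count": "2", "idlist": ["600001", "600002"]}}]
[https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esummary.fcgi?db=omim&id=600001,600002&retmode=json]–>[{"result": {"600001": {"title": "EXAMPLE DISEASE SYNDROME 1; EDS1 caused by mutation in GXB2"}, "600002": {"title": "EXAMPLE DISEASE SYNDROME 2; EDS2 caused by mutation in ZQT7"}}}]
Answer: GXB2, ZQT7
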