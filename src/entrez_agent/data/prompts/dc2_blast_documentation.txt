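You can align a nucleotide sequence to sequence databases with the BLAST URL
API at https://blast.ncbi.nlm.nih.gov/blast/Blast.cgi. Every call must include
a CMD parameter. Submit a query with CMD=Put, giving the search program with
PROGRAM (e.g. blastn), the database with DATABASE (e.g. nt for nucleotides,
including the human genome), and the sequence with QUERY. The Put call returns
an RID; retrieve the finished results with a second call using CMD=Get and
RID={rid}.
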