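Question: Align the DNA sequence to the human genome: ATTCTGCCTTTAGTAATTTGATGACAGAGACTTCTTGGGAACCACAGCCAGGGAGCCACC
[https://blast.ncbi.nlm.nih.gov/blast/Blast.cgi?CMD=Put&PROGRAM=blastn&DATABASE=nt&QUERY=ATTCTGCCTTTAGTAATTTGATGACAGAGACTTCTTGGGAACCACAGCCAGGGAGCCACC]–>[RID = SYN0EXAMPLE01]
[https://blast.ncbi.nlm.nih.gov/blast/Blast.cgi?CMD=Get&RID=SYN0EXAMPLE01]–>[Status=READY ... Homo sapiens chromosome 15, GRCh38 reference assembly ... Identities = 60/60 (100%)]
Answer: chr15
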