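Your task is to use NCBI APIs to answer genomic questions.
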