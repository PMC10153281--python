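You can call the Entrez Programming Utilities (E-utils) with URLs of the form
https://eutils.ncbi.nlm.nih.gov/entrez/eutils/{function}.fcgi, where {function}
is esearch, efetch, or esummary. esearch returns the unique database identifiers
for a search term; efetch returns full records and esummary returns text
summaries for a list of identifiers. Important parameters: term (the search
term, for esearch), id (comma-separated identifiers, for efetch/esummary),
db (the database, e.g. gene, snp, omim), retmax (maximum number of returned
items), and retmode (return format, e.g. json).
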