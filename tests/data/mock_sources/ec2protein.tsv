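#protein_accession	ec_number
NP_100004.1	1.1.1.4
NP_100005.1	1.1.1.3
NP_100006.1	1.1.1.2
NP_100008.1	1.1.1.1
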