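ID   1.1.1.1
DE   Mock enzyme 1.1.1.1.
//
ID   1.1.1.2
DE   Mock enzyme 1.1.1.2.
//
ID   1.1.1.3
DE   Mock enzyme 1.1.1.3.
//
ID   1.1.1.4
DE   Mock enzyme 1.1.1.4.
//
ID   2.2.2.2
DE   Transferred entry: 1.1.1.1.
//
ID   3.3.3.3
DE   Deleted entry.
//
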