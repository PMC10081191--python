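C00002
C00003
C00005
C00006
C99999
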