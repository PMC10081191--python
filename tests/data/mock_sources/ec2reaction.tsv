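ec:1.1.1.1	rn:R00003
ec:1.1.1.2	rn:R00001
ec:1.1.1.2	rn:R00002
ec:1.1.1.3	rn:R00004
ec:1.1.1.3	rn:R00006
ec:1.1.1.4	rn:R00005
ec:2.2.2.2	rn:R00001
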