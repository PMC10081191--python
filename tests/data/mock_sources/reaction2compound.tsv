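rn:R00001	cpd:C00005
rn:R00001	cpd:C00008
rn:R00001	cpd:C00010
rn:R00002	cpd:C00002
rn:R00002	cpd:C00009
rn:R00003	cpd:C00003
rn:R00003	cpd:C00006
rn:R00004	cpd:C00007
rn:R00004	cpd:C00008
rn:R00005	cpd:C00002
rn:R00005	cpd:C00011
rn:R00006	cpd:C00006
rn:R00006	cpd:C00010
rn:R00006	cpd:C00011
rn:R00001	gl:G00001
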