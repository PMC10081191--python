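#tax_id	GeneID	GO_ID	Evidence	Qualifier	GO_term	PubMed	Category
9606	1001	GO:1000003	IDA	-	mock	-	Process
9606	1002	GO:1000006	IDA	-	mock	-	Process
9606	1003	GO:1000001	IDA	-	mock	-	Process
9606	1004	GO:0008152	IDA	-	mock	-	Process
9606	1005	GO:0008152	IDA	-	mock	-	Process
9606	1005	GO:1000006	IDA	-	mock	-	Process
9606	1006	GO:0008152	IDA	-	mock	-	Process
9606	1001	GO:1000007	IEA	NOT	mock	-	Process
10090	1001	GO:0008152	IDA	-	mock	-	Process
9606	1007	GO:0099999	IDA	-	mock	-	Process
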