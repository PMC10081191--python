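#tax_id	GeneID	status	RNA_nucleotide_accession.version	RNA_nucleotide_gi	protein_accession.version	protein_gi	genomic_nucleotide_accession.version	genomic_nucleotide_gi	start_position_on_the_genomic_accession	end_position_on_the_genomic_accession	orientation	assembly	mature_peptide_accession.version	mature_peptide_gi	Symbol
9606	1001	REVIEWED	NM_100001.1	111	NP_100001.2	222	-	-	-	-	?	-	-	-	GENE1001
9606	1001	REVIEWED	NM_100002.2	111	NP_100002.1	222	-	-	-	-	?	-	-	-	GENE1001
9606	1001	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1001
9606	1002	REVIEWED	NM_100003.1	111	NP_100003.3	222	-	-	-	-	?	-	-	-	GENE1002
9606	1002	REVIEWED	NM_100004.2	111	NP_100004.3	222	-	-	-	-	?	-	-	-	GENE1002
9606	1002	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1002
9606	1003	REVIEWED	NM_100005.1	111	NP_100005.1	222	-	-	-	-	?	-	-	-	GENE1003
9606	1003	REVIEWED	NM_100006.3	111	NP_100006.3	222	-	-	-	-	?	-	-	-	GENE1003
9606	1003	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1003
9606	1004	REVIEWED	NM_100007.1	111	NP_100007.2	222	-	-	-	-	?	-	-	-	GENE1004
9606	1004	REVIEWED	NM_100008.1	111	NP_100008.3	222	-	-	-	-	?	-	-	-	GENE1004
9606	1004	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1004
9606	1005	REVIEWED	NM_100009.1	111	NP_100009.3	222	-	-	-	-	?	-	-	-	GENE1005
9606	1005	REVIEWED	NM_100010.1	111	NP_100010.3	222	-	-	-	-	?	-	-	-	GENE1005
9606	1005	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1005
9606	1006	REVIEWED	NM_100011.2	111	NP_100011.3	222	-	-	-	-	?	-	-	-	GENE1006
9606	1006	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1006
9606	1007	REVIEWED	NM_100012.2	111	NP_100012.2	222	-	-	-	-	?	-	-	-	GENE1007
9606	1007	REVIEWED	NM_100013.2	111	NP_100013.3	222	-	-	-	-	?	-	-	-	GENE1007
9606	1007	REVIEWED	-	-	-	-	NC_000001.11	333	1	2	+	-	-	-	GENE1007
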