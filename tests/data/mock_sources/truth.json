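{
 "background_n": 9,
 "compounds": [
  "C00002",
  "C00003",
  "C00005",
  "C00006",
  "C00007",
  "C00008",
  "C00009",
  "C00010",
  "C00011"
 ],
 "edges": {
  "ec_reaction": [
   [
    "1.1.1.1",
    "R00003"
   ],
   [
    "1.1.1.2",
    "R00001"
   ],
   [
    "1.1.1.2",
    "R00002"
   ],
   [
    "1.1.1.3",
    "R00004"
   ],
   [
    "1.1.1.3",
    "R00006"
   ],
   [
    "1.1.1.4",
    "R00005"
   ]
  ],
  "gene_go": [
   [
    1001,
    "GO:1000003"
   ],
   [
    1002,
    "GO:1000006"
   ],
   [
    1003,
    "GO:1000001"
   ],
   [
    1004,
    "GO:0008152"
   ],
   [
    1005,
    "GO:0008152"
   ],
   [
    1005,
    "GO:1000006"
   ],
   [
    1006,
    "GO:0008152"
   ]
  ],
  "gene_protein": [
   [
    1001,
    "NP_100001"
   ],
   [
    1001,
    "NP_100002"
   ],
   [
    1002,
    "NP_100003"
   ],
   [
    1002,
    "NP_100004"
   ],
   [
    1003,
    "NP_100005"
   ],
   [
    1003,
    "NP_100006"
   ],
   [
    1004,
    "NP_100007"
   ],
   [
    1004,
    "NP_100008"
   ],
   [
    1005,
    "NP_100009"
   ],
   [
    1005,
    "NP_100010"
   ],
   [
    1006,
    "NP_100011"
   ]
  ],
  "gene_transcript": [
   [
    1001,
    "NM_100001"
   ],
   [
    1001,
    "NM_100002"
   ],
   [
    1002,
    "NM_100003"
   ],
   [
    1002,
    "NM_100004"
   ],
   [
    1003,
    "NM_100005"
   ],
   [
    1003,
    "NM_100006"
   ],
   [
    1004,
    "NM_100007"
   ],
   [
    1004,
    "NM_100008"
   ],
   [
    1005,
    "NM_100009"
   ],
   [
    1005,
    "NM_100010"
   ],
   [
    1006,
    "NM_100011"
   ]
  ],
  "protein_ec": [
   [
    "NP_100004",
    "1.1.1.4"
   ],
   [
    "NP_100005",
    "1.1.1.3"
   ],
   [
    "NP_100006",
    "1.1.1.2"
   ],
   [
    "NP_100008",
    "1.1.1.1"
   ]
  ],
  "reaction_compound": [
   [
    "R00001",
    "C00005"
   ],
   [
    "R00001",
    "C00008"
   ],
   [
    "R00001",
    "C00010"
   ],
   [
    "R00002",
    "C00002"
   ],
   [
    "R00002",
    "C00009"
   ],
   [
    "R00003",
    "C00003"
   ],
   [
    "R00003",
    "C00006"
   ],
   [
    "R00004",
    "C00007"
   ],
   [
    "R00004",
    "C00008"
   ],
   [
    "R00005",
    "C00002"
   ],
   [
    "R00005",
    "C00011"
   ],
   [
    "R00006",
    "C00006"
   ],
   [
    "R00006",
    "C00010"
   ],
   [
    "R00006",
    "C00011"
   ]
  ],
  "transcript_protein": [
   [
    "NM_100001",
    "NP_100001"
   ],
   [
    "NM_100002",
    "NP_100002"
   ],
   [
    "NM_100003",
    "NP_100003"
   ],
   [
    "NM_100004",
    "NP_100004"
   ],
   [
    "NM_100005",
    "NP_100005"
   ],
   [
    "NM_100006",
    "NP_100006"
   ],
   [
    "NM_100007",
    "NP_100007"
   ],
   [
    "NM_100008",
    "NP_100008"
   ],
   [
    "NM_100009",
    "NP_100009"
   ],
   [
    "NM_100010",
    "NP_100010"
   ],
   [
    "NM_100011",
    "NP_100011"
   ]
  ]
 },
 "enzymes": [
  "1.1.1.1",
  "1.1.1.2",
  "1.1.1.3",
  "1.1.1.4"
 ],
 "genes": [
  1001,
  1002,
  1003,
  1004,
  1005,
  1006
 ],
 "proteins": [
  "NP_100001",
  "NP_100002",
  "NP_100003",
  "NP_100004",
  "NP_100005",
  "NP_100006",
  "NP_100007",
  "NP_100008",
  "NP_100009",
  "NP_100010",
  "NP_100011"
 ],
 "reactions": [
  "R00001",
  "R00002",
  "R00003",
  "R00004",
  "R00005",
  "R00006"
 ],
 "term_to_compounds": {
  "GO:0008152": [
   "C00003",
   "C00006"
  ],
  "GO:1000001": [
   "C00002",
   "C00005",
   "C00006",
   "C00007",
   "C00008",
   "C00009",
   "C00010",
   "C00011"
  ],
  "GO:1000006": [
   "C00002",
   "C00011"
  ]
 },
 "term_to_genes": {
  "GO:0008152": [
   1004,
   1005,
   1006
  ],
  "GO:1000001": [
   1003
  ],
  "GO:1000003": [
   1001
  ],
  "GO:1000006": [
   1002,
   1005
  ]
 },
 "terms": [
  "GO:0008152",
  "GO:1000001",
  "GO:1000002",
  "GO:1000003",
  "GO:1000004",
  "GO:1000005",
  "GO:1000006",
  "GO:1000007"
 ],
 "transcripts": [
  "NM_100001",
  "NM_100002",
  "NM_100003",
  "NM_100004",
  "NM_100005",
  "NM_100006",
  "NM_100007",
  "NM_100008",
  "NM_100009",
  "NM_100010",
  "NM_100011"
 ]
}
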