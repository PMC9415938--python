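{
 "gaf": {
  "ancestor_length": 174,
  "cys_col": 88,
  "adj_col": 89,
  "triad_cols": [
   52,
   83,
   126
  ],
  "groups": {
   "CcaS": {
    "trim": [
     12,
     168
    ],
    "cys_pos": 76,
    "adj_pos": 77,
    "triad_pos": [
     40,
     71,
     114
    ],
    "adj_residue": "L",
    "triad_residues": "EDH"
   },
   "RcaE": {
    "trim": [
     4,
     169
    ],
    "cys_pos": 84,
    "adj_pos": 85,
    "triad_pos": [
     48,
     79,
     122
    ],
    "adj_residue": "L",
    "triad_residues": "EDH"
   },
   "RfpA": {
    "trim": [
     0,
     170
    ],
    "cys_pos": 88,
    "adj_pos": 89,
    "triad_pos": [
     52,
     83,
     126
    ],
    "adj_residue": "H",
    "triad_residues": "QNH"
   }
  }
 },
 "pbp": {
  "motif_cols": [
   150,
   151,
   152,
   153,
   154
  ],
  "cys_col": 153,
  "canonical_motif": "ELACS",
  "farlip_motif": "PEDVT"
 },
 "photoreceptor_gaf_offset": {
  "ccaS": 30,
  "rcaE": 25,
  "rfpA": 133
 },
 "frozen_positions": {
  "ccaS": [
   106,
   107,
   70,
   101,
   144
  ],
  "rcaE": [
   109,
   110,
   73,
   104,
   147
  ],
  "rfpA": [
   221,
   222,
   185,
   216,
   259
  ],
  "cpcL": [
   196,
   197,
   198,
   199,
   200,
   201,
   202,
   203,
   204,
   205,
   206,
   207,
   208,
   209,
   210,
   211,
   212,
   213,
   214,
   215,
   216,
   217,
   218,
   219,
   220,
   221,
   222
  ],
  "apcE_canonical": [
   150,
   151,
   152,
   153,
   154
  ],
  "apcE_farlip": [
   150,
   151,
   152,
   153,
   154
  ],
  "apcA": [
   150,
   151,
   152,
   153,
   154
  ],
  "apcB": [
   150,
   151,
   152,
   153,
   154
  ],
  "apcD": [
   150,
   151,
   152,
   153,
   154
  ],
  "cpcA": [
   150,
   151,
   152,
   153,
   154
  ],
  "cpcB": [
   150,
   151,
   152,
   153,
   154
  ],
  "cpeA": [
   150,
   151,
   152,
   153,
   154
  ],
  "cpeB": [
   150,
   151,
   152,
   153,
   154
  ],
  "pecA": [
   150,
   151,
   152,
   153,
   154
  ],
  "pecB": [
   150,
   151,
   152,
   153,
   154
  ]
 }
}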