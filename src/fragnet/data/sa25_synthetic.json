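{
 "name": "SA25-synthetic",
 "comment": "Synthetic 25-letter structural alphabet: ideal-geometry tetrapeptide C-alpha traces at 25 Ramachandran (phi,psi) points. Stand-in for literature fragment libraries; not derived from PDB statistics.",
 "prototypes": [
  {
   "letter": "A",
   "ca": [
    [
     -0.1483,
     -2.7818,
     -1.4149
    ],
    [
     0.2931,
     0.8686,
     -2.3892
    ],
    [
     -1.2425,
     2.0559,
     0.8822
    ],
    [
     1.0976,
     -0.1427,
     2.9219
    ]
   ]
  },
  {
   "letter": "B",
   "ca": [
    [
     -0.086,
     -2.7459,
     -1.4777
    ],
    [
     0.2794,
     0.934,
     -2.3691
    ],
    [
     -1.2764,
     2.0178,
     0.9286
    ],
    [
     1.083,
     -0.2059,
     2.9182
    ]
   ]
  },
  {
   "letter": "C",
   "ca": [
    [
     -0.1776,
     -2.7007,
     -1.5704
    ],
    [
     0.0934,
     1.0158,
     -2.3345
    ],
    [
     -1.2811,
     1.9087,
     1.0982
    ],
    [
     1.3653,
     -0.2238,
     2.8067
    ]
   ]
  },
  {
   "letter": "D",
   "ca": [
    [
     -0.2688,
     -2.8184,
     -1.3579
    ],
    [
     0.255,
     0.8001,
     -2.4077
    ],
    [
     -1.1953,
     2.0784,
     0.8684
    ],
    [
     1.209,
     -0.0601,
     2.8973
    ]
   ]
  },
  {
   "letter": "E",
   "ca": [
    [
     -0.2391,
     -2.6622,
     -1.6665
    ],
    [
     -0.0473,
     1.0851,
     -2.292
    ],
    [
     -1.2768,
     1.8112,
     1.2338
    ],
    [
     1.5631,
     -0.234,
     2.7247
    ]
   ]
  },
  {
   "letter": "F",
   "ca": [
    [
     -1.2918,
     -2.7685,
     -1.2437
    ],
    [
     -1.1197,
     0.9864,
     -1.8277
    ],
    [
     -0.6291,
     1.1879,
     1.9391
    ],
    [
     3.0406,
     0.5941,
     1.1322
    ]
   ]
  },
  {
   "letter": "G",
   "ca": [
    [
     -0.6187,
     -2.6277,
     -1.7847
    ],
    [
     -0.5299,
     1.1595,
     -2.1295
    ],
    [
     -1.1239,
     1.5174,
     1.6107
    ],
    [
     2.2726,
     -0.0492,
     2.3035
    ]
   ]
  },
  {
   "letter": "H",
   "ca": [
    [
     -0.9574,
     -2.6208,
     -1.913
    ],
    [
     -0.911,
     1.1829,
     -1.913
    ],
    [
     -0.8984,
     1.2276,
     1.8907
    ],
    [
     2.7668,
     0.2104,
     1.9354
    ]
   ]
  },
  {
   "letter": "I",
   "ca": [
    [
     -1.6632,
     -2.7462,
     -1.799
    ],
    [
     -1.5419,
     1.0284,
     -1.3433
    ],
    [
     -0.1834,
     0.6439,
     2.1889
    ],
    [
     3.3885,
     1.074,
     0.9534
    ]
   ]
  },
  {
   "letter": "J",
   "ca": [
    [
     -2.5879,
     -3.2996,
     -1.0241
    ],
    [
     -1.9204,
     0.2632,
     0.1296
    ],
    [
     1.8025,
     -0.3181,
     0.6509
    ],
    [
     2.7057,
     3.3545,
     0.2436
    ]
   ]
  },
  {
   "letter": "K",
   "ca": [
    [
     -3.1946,
     -3.2464,
     -0.3157
    ],
    [
     -1.6904,
     -0.0081,
     0.9962
    ],
    [
     1.1682,
     0.7055,
     -1.4098
    ],
    [
     3.7168,
     2.549,
     0.7294
    ]
   ]
  },
  {
   "letter": "L",
   "ca": [
    [
     -3.3097,
     -3.1851,
     1.0988
    ],
    [
     -1.0038,
     -0.2578,
     1.8629
    ],
    [
     0.3161,
     1.8459,
     -1.0185
    ],
    [
     3.9975,
     1.597,
     -1.9432
    ]
   ]
  },
  {
   "letter": "M",
   "ca": [
    [
     -2.8155,
     -3.2762,
     1.5944
    ],
    [
     -0.4013,
     -0.3909,
     2.1574
    ],
    [
     0.205,
     2.1292,
     -0.6267
    ],
    [
     3.0118,
     1.5379,
     -3.1251
    ]
   ]
  },
  {
   "letter": "N",
   "ca": [
    [
     -3.6519,
     -3.2041,
     0.2043
    ],
    [
     -1.565,
     -0.1919,
     1.2248
    ],
    [
     0.884,
     1.1912,
     -1.3364
    ],
    [
     4.333,
     2.2048,
     -0.0926
    ]
   ]
  },
  {
   "letter": "O",
   "ca": [
    [
     -3.5975,
     -3.3221,
     -0.5504
    ],
    [
     -1.7841,
     -0.2037,
     0.6569
    ],
    [
     1.6179,
     0.4497,
     -0.9146
    ],
    [
     3.7638,
     3.0761,
     0.8081
    ]
   ]
  },
  {
   "letter": "P",
   "ca": [
    [
     -3.8795,
     -3.3226,
     -0.4419
    ],
    [
     -1.7927,
     -0.3104,
     0.5786
    ],
    [
     1.6556,
     0.5162,
     -0.7984
    ],
    [
     4.0167,
     3.1168,
     0.6617
    ]
   ]
  },
  {
   "letter": "Q",
   "ca": [
    [
     -4.0565,
     -3.3337,
     -0.4327
    ],
    [
     -1.8166,
     -0.3808,
     0.4236
    ],
    [
     1.7597,
     0.4711,
     -0.5532
    ],
    [
     4.1134,
     3.2435,
     0.5622
    ]
   ]
  },
  {
   "letter": "R",
   "ca": [
    [
     -4.2388,
     -3.3309,
     -0.2572
    ],
    [
     -1.8247,
     -0.4456,
     0.3058
    ],
    [
     1.7884,
     0.5025,
     -0.4131
    ],
    [
     4.2751,
     3.2741,
     0.3645
    ]
   ]
  },
  {
   "letter": "S",
   "ca": [
    [
     -4.3373,
     -3.3219,
     0.0292
    ],
    [
     -1.8256,
     -0.4744,
     0.2605
    ],
    [
     1.7755,
     0.5435,
     -0.422
    ],
    [
     4.3874,
     3.2528,
     0.1324
    ]
   ]
  },
  {
   "letter": "T",
   "ca": [
    [
     -4.0542,
     -3.2162,
     0.4569
    ],
    [
     -1.6401,
     -0.3309,
     1.0199
    ],
    [
     1.1204,
     1.1029,
     -1.1696
    ],
    [
     4.5739,
     2.4443,
     -0.3072
    ]
   ]
  },
  {
   "letter": "U",
   "ca": [
    [
     -0.1483,
     -2.7818,
     1.4149
    ],
    [
     0.2931,
     0.8686,
     2.3892
    ],
    [
     -1.2425,
     2.0559,
     -0.8822
    ],
    [
     1.0976,
     -0.1427,
     -2.9219
    ]
   ]
  },
  {
   "letter": "V",
   "ca": [
    [
     -0.5624,
     -2.665,
     1.6436
    ],
    [
     -0.3996,
     1.0935,
     2.2066
    ],
    [
     -1.1592,
     1.6398,
     -1.4805
    ],
    [
     2.1213,
     -0.0683,
     -2.3697
    ]
   ]
  },
  {
   "letter": "W",
   "ca": [
    [
     -3.0669,
     -3.1467,
     -0.6445
    ],
    [
     -1.1574,
     -0.0657,
     -1.7982
    ],
    [
     0.2135,
     1.7024,
     1.2783
    ],
    [
     4.0109,
     1.51,
     1.1645
    ]
   ]
  },
  {
   "letter": "X",
   "ca": [
    [
     -3.0121,
     -3.0121,
     -1.911
    ],
    [
     -1.9393,
     0.3935,
     -0.5991
    ],
    [
     1.0172,
     0.2107,
     1.7875
    ],
    [
     3.9341,
     2.4079,
     0.7225
    ]
   ]
  },
  {
   "letter": "Y",
   "ca": [
    [
     -3.0237,
     -3.1395,
     -2.4954
    ],
    [
     -0.5681,
     -0.2703,
     -2.0398
    ],
    [
     0.4392,
     1.8634,
     0.944
    ],
    [
     3.1525,
     1.5463,
     3.5912
    ]
   ]
  }
 ],
 "helix_class": [
  "A",
  "B",
  "C",
  "D",
  "E"
 ],
 "sheet_class": [
  "N",
  "O",
  "P",
  "Q",
  "R",
  "S",
  "T"
 ]
}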