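{
 "family_map": {
  "ASV_0000": "AkkermansiaceaeLike",
  "ASV_0001": "AkkermansiaceaeLike",
  "ASV_0002": "AkkermansiaceaeLike",
  "ASV_0003": "AkkermansiaceaeLike",
  "ASV_0004": "AkkermansiaceaeLike",
  "ASV_0005": "AkkermansiaceaeLike",
  "ASV_0006": "MuribaculaceaeLike",
  "ASV_0007": "MuribaculaceaeLike",
  "ASV_0008": "MuribaculaceaeLike",
  "ASV_0009": "MuribaculaceaeLike",
  "ASV_0010": "MuribaculaceaeLike",
  "ASV_0011": "MuribaculaceaeLike",
  "ASV_0012": "MuribaculaceaeLike",
  "ASV_0013": "MuribaculaceaeLike",
  "ASV_0014": "MuribaculaceaeLike",
  "ASV_0015": "PairedMarker",
  "ASV_0016": "PairedMarker",
  "ASV_0017": "PairedMarker",
  "ASV_0018": "PairedMarker",
  "ASV_0019": "Other",
  "ASV_0020": "Other",
  "ASV_0021": "Other",
  "ASV_0022": "Other",
  "ASV_0023": "Other",
  "ASV_0024": "Other",
  "ASV_0025": "Other",
  "ASV_0026": "Other",
  "ASV_0027": "Other",
  "ASV_0028": "Other",
  "ASV_0029": "Other",
  "ASV_0030": "Other",
  "ASV_0031": "Other",
  "ASV_0032": "Other",
  "ASV_0033": "Other",
  "ASV_0034": "Other",
  "ASV_0035": "Other",
  "ASV_0036": "Other",
  "ASV_0037": "Other",
  "ASV_0038": "Other",
  "ASV_0039": "Other",
  "ASV_0040": "Other",
  "ASV_0041": "Other",
  "ASV_0042": "Other",
  "ASV_0043": "Other",
  "ASV_0044": "Other",
  "ASV_0045": "Other",
  "ASV_0046": "Other",
  "ASV_0047": "Other",
  "ASV_0048": "Other",
  "ASV_0049": "Other",
  "ASV_0050": "Other",
  "ASV_0051": "Other",
  "ASV_0052": "Other",
  "ASV_0053": "Other",
  "ASV_0054": "Other",
  "ASV_0055": "Other",
  "ASV_0056": "Other",
  "ASV_0057": "Other",
  "ASV_0058": "Other",
  "ASV_0059": "Other"
 },
 "group_effects": {
  "HFHC-Air": 0.72,
  "HFHC-IHC": 1.2,
  "RC-Air": 0.0
 },
 "ihc_metabolites": [
  "MET_0010",
  "MET_0011",
  "MET_0012",
  "MET_0013",
  "MET_0014",
  "MET_0015",
  "MET_0016",
  "MET_0017",
  "MET_0018",
  "MET_0019"
 ],
 "latent_factors": {
  "index": [
   "RC-Air.m00.t00",
   "RC-Air.m00.t01",
   "RC-Air.m00.t02",
   "RC-Air.m00.t03",
   "RC-Air.m00.t04",
   "RC-Air.m00.t05",
   "RC-Air.m01.t00",
   "RC-Air.m01.t01",
   "RC-Air.m01.t02",
   "RC-Air.m01.t03",
   "RC-Air.m01.t04",
   "RC-Air.m01.t05",
   "RC-Air.m02.t00",
   "RC-Air.m02.t01",
   "RC-Air.m02.t02",
   "RC-Air.m02.t03",
   "RC-Air.m02.t04",
   "RC-Air.m02.t05",
   "HFHC-Air.m00.t00",
   "HFHC-Air.m00.t01",
   "HFHC-Air.m00.t02",
   "HFHC-Air.m00.t03",
   "HFHC-Air.m00.t04",
   "HFHC-Air.m00.t05",
   "HFHC-Air.m01.t00",
   "HFHC-Air.m01.t01",
   "HFHC-Air.m01.t02",
   "HFHC-Air.m01.t03",
   "HFHC-Air.m01.t04",
   "HFHC-Air.m01.t05",
   "HFHC-Air.m02.t00",
   "HFHC-Air.m02.t01",
   "HFHC-Air.m02.t02",
   "HFHC-Air.m02.t03",
   "HFHC-Air.m02.t04",
   "HFHC-Air.m02.t05",
   "HFHC-IHC.m00.t00",
   "HFHC-IHC.m00.t01",
   "HFHC-IHC.m00.t02",
   "HFHC-IHC.m00.t03",
   "HFHC-IHC.m00.t04",
   "HFHC-IHC.m00.t05",
   "HFHC-IHC.m01.t00",
   "HFHC-IHC.m01.t01",
   "HFHC-IHC.m01.t02",
   "HFHC-IHC.m01.t03",
   "HFHC-IHC.m01.t04",
   "HFHC-IHC.m01.t05",
   "HFHC-IHC.m02.t00",
   "HFHC-IHC.m02.t01",
   "HFHC-IHC.m02.t02",
   "HFHC-IHC.m02.t03",
   "HFHC-IHC.m02.t04",
   "HFHC-IHC.m02.t05"
  ],
  "values": [
   [
    0.222695,
    0.107018
   ],
   [
    0.071689,
    -0.009977
   ],
   [
    -0.156978,
    0.639247
   ],
   [
    0.379996,
    0.108918
   ],
   [
    -0.002275,
    -0.110233
   ],
   [
    -0.145695,
    0.072068
   ],
   [
    -0.813372,
    0.685487
   ],
   [
    0.192859,
    -0.337653
   ],
   [
    -0.323684,
    0.959133
   ],
   [
    -0.19699,
    -0.305774
   ],
   [
    0.380675,
    0.39209
   ],
   [
    -0.070317,
    -0.132749
   ],
   [
    0.297196,
    -0.923791
   ],
   [
    0.343227,
    -0.857751
   ],
   [
    0.101539,
    -0.799214
   ],
   [
    -0.240842,
    -0.714451
   ],
   [
    0.044537,
    -1.158584
   ],
   [
    -0.406899,
    -1.561334
   ],
   [
    0.138349,
    -0.379157
   ],
   [
    -0.463652,
    -0.901016
   ],
   [
    0.794159,
    -1.080124
   ],
   [
    0.603413,
    -1.06223
   ],
   [
    0.661392,
    0.017445
   ],
   [
    0.352498,
    -0.481071
   ],
   [
    0.054668,
    0.379627
   ],
   [
    -0.138772,
    0.070743
   ],
   [
    0.2018,
    -0.348341
   ],
   [
    0.914961,
    -0.111079
   ],
   [
    0.889388,
    0.863861
   ],
   [
    0.56486,
    -0.403212
   ],
   [
    0.531698,
    -0.412239
   ],
   [
    0.057675,
    -1.42996
   ],
   [
    0.139122,
    -1.365269
   ],
   [
    0.212436,
    -0.365777
   ],
   [
    0.547439,
    0.213847
   ],
   [
    0.821276,
    -0.678465
   ],
   [
    0.159274,
    -0.503773
   ],
   [
    0.17216,
    -0.645012
   ],
   [
    0.799726,
    -0.435185
   ],
   [
    0.411824,
    -0.334429
   ],
   [
    1.19627,
    -0.498661
   ],
   [
    0.95261,
    -1.236572
   ],
   [
    0.149832,
    0.094239
   ],
   [
    -0.583561,
    0.535764
   ],
   [
    0.717934,
    0.398346
   ],
   [
    0.616407,
    0.668246
   ],
   [
    0.873621,
    0.609133
   ],
   [
    1.015661,
    -0.20007
   ],
   [
    0.04476,
    0.523511
   ],
   [
    0.819511,
    0.00291
   ],
   [
    0.378417,
    0.159948
   ],
   [
    0.415545,
    -0.566312
   ],
   [
    0.6393,
    1.314298
   ],
   [
    1.144608,
    -0.085887
   ]
  ]
 },
 "planted_pairs": [
  [
   "ASV_0015",
   "MET_0020"
  ],
  [
   "ASV_0016",
   "MET_0021"
  ],
  [
   "ASV_0017",
   "MET_0022"
  ],
  [
   "ASV_0018",
   "MET_0023"
  ]
 ],
 "rc_metabolites": [
  "MET_0000",
  "MET_0001",
  "MET_0002",
  "MET_0003",
  "MET_0004",
  "MET_0005",
  "MET_0006",
  "MET_0007",
  "MET_0008",
  "MET_0009"
 ],
 "seeds": {
  "truth_seed": 20260929
 }
}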