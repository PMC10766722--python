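{
 "entries": [
  {
   "allergen_name": "Milk caseinate",
   "parent_protein_accessions": [
    "P02662"
   ],
   "markers": [
    {
     "code": "mc-FFV",
     "sequence": "FFVAPFPEVFGK",
     "role": "QTM",
     "label_shift": 8.0,
     "transitions": [
      [
       692.87,
       450.27
      ],
      [
       692.87,
       579.31
      ],
      [
       692.87,
       676.37
      ],
      [
       692.87,
       823.43
      ]
     ]
    },
    {
     "code": "mc-NAV",
     "sequence": "NAVPITPTLNR",
     "role": "QLM",
     "label_shift": 10.0,
     "transitions": [
      [
       598.34,
       503.29
      ],
      [
       598.34,
       600.35
      ],
      [
       598.34,
       701.39
      ],
      [
       598.34,
       814.48
      ]
     ]
    }
   ],
   "cMM": 23615.0,
   "u_MM": 370.0,
   "cCF": 0.374,
   "u_CF": 0.009
  },
  {
   "allergen_name": "Milk whey",
   "parent_protein_accessions": [
    "P02754"
   ],
   "markers": [
    {
     "code": "mw-VLV",
     "sequence": "VLVLDTDYK",
     "role": "QTM",
     "label_shift": 8.0,
     "transitions": [
      [
       533.29,
       526.25
      ],
      [
       533.29,
       641.28
      ],
      [
       533.29,
       754.36
      ],
      [
       533.29,
       853.43
      ]
     ]
    },
    {
     "code": "mw-IDA",
     "sequence": "IDALNENK",
     "role": "QLM",
     "label_shift": 8.0,
     "transitions": [
      [
       458.74,
       504.24
      ],
      [
       458.74,
       617.33
      ],
      [
       458.74,
       688.36
      ],
      [
       458.74,
       803.39
      ]
     ]
    }
   ],
   "cMM": 18281.0,
   "u_MM": 64.0,
   "cCF": 0.193,
   "u_CF": 0.002
  },
  {
   "allergen_name": "Egg white",
   "parent_protein_accessions": [
    "P01012"
   ],
   "markers": [
    {
     "code": "ew-ISQ",
     "sequence": "ISQAVHAAHAEINEAGR",
     "role": "QTM",
     "label_shift": 10.0,
     "transitions": [
      [
       887.45,
       432.22
      ],
      [
       887.45,
       546.26
      ],
      [
       887.45,
       659.35
      ],
      [
       887.45,
       788.39
      ]
     ]
    },
    {
     "code": "ew-GGL",
     "sequence": "GGLEPINFQTAADQAR",
     "role": "QLM",
     "label_shift": 10.0,
     "transitions": [
      [
       844.42,
       489.24
      ],
      [
       844.42,
       560.28
      ],
      [
       844.42,
       631.32
      ],
      [
       844.42,
       732.36
      ]
     ]
    }
   ],
   "cMM": 42750.0,
   "u_MM": 150.0,
   "cCF": 0.468,
   "u_CF": 0.003,
   "compliance_cf": 0.54
  },
  {
   "allergen_name": "Egg yolk",
   "parent_protein_accessions": [
    "P87498",
    "P02845"
   ],
   "markers": [
    {
     "code": "ey-ATA",
     "sequence": "ATAVSLLEWQR",
     "role": "QTM",
     "label_shift": 10.0,
     "transitions": [
      [
       637.35,
       618.3
      ],
      [
       637.35,
       731.38
      ],
      [
       637.35,
       844.47
      ],
      [
       637.35,
       931.5
      ]
     ]
    },
    {
     "code": "ey-NIG",
     "sequence": "NIGELGVEK",
     "role": "QLM",
     "label_shift": 8.0,
     "transitions": [
      [
       479.76,
       432.25
      ],
      [
       479.76,
       545.33
      ],
      [
       479.76,
       674.37
      ],
      [
       479.76,
       731.39
      ]
     ]
    }
   ],
   "cMM": 204000.0,
   "u_MM": 1100.0,
   "cCF": 0.3,
   "u_CF": 0.01
  },
  {
   "allergen_name": "Peanut",
   "parent_protein_accessions": [
    "O82580"
   ],
   "markers": [
    {
     "code": "p-TAN",
     "sequence": "TANDLNLLILR",
     "role": "QTM",
     "label_shift": 10.0,
     "transitions": [
      [
       628.37,
       514.37
      ],
      [
       628.37,
       627.46
      ],
      [
       628.37,
       741.5
      ],
      [
       628.37,
       854.58
      ]
     ]
    },
    {
     "code": "p-SPD",
     "sequence": "SPDIYNPQAGSLK",
     "role": "QLM",
     "label_shift": 8.0,
     "transitions": [
      [
       695.35,
       404.25
      ],
      [
       695.35,
       475.29
      ],
      [
       695.35,
       603.35
      ],
      [
       695.35,
       700.4
      ]
     ]
    }
   ],
   "cMM": 58000.0,
   "u_MM": 300.0,
   "cCF": 0.695,
   "u_CF": 0.006
  },
  {
   "allergen_name": "Soybean",
   "parent_protein_accessions": [
    "P04776"
   ],
   "markers": [
    {
     "code": "s-VLI",
     "sequence": "VLIVPQNFVVAAR",
     "role": "QTM",
     "label_shift": 10.0,
     "transitions": [
      [
       713.43,
       416.26
      ],
      [
       713.43,
       515.33
      ],
      [
       713.43,
       662.4
      ],
      [
       713.43,
       776.44
      ]
     ]
    },
    {
     "code": "s-VFD",
     "sequence": "VFDGELQEGR",
     "role": "QLM",
     "label_shift": 10.0,
     "transitions": [
      [
       575.28,
       489.24
      ],
      [
       575.28,
       602.33
      ],
      [
       575.28,
       731.37
      ],
      [
       575.28,
       788.39
      ]
     ]
    }
   ],
   "cMM": 55700.0,
   "u_MM": 300.0,
   "cCF": 0.3,
   "u_CF": 0.024
  },
  {
   "allergen_name": "Hazelnut",
   "parent_protein_accessions": [
    "A0A0A0P7E3"
   ],
   "markers": [
    {
     "code": "h-ALP",
     "sequence": "ALPDDVLANAFQISR",
     "role": "QTM",
     "label_shift": 10.0,
     "transitions": [
      [
       815.43,
       503.29
      ],
      [
       815.43,
       650.36
      ],
      [
       815.43,
       721.4
      ],
      [
       815.43,
       835.44
      ]
     ]
    },
    {
     "code": "h-ADIY",
     "sequence": "ADIYTEQVGR",
     "role": "QLM",
     "label_shift": 10.0,
     "transitions": [
      [
       576.29,
       459.27
      ],
      [
       576.29,
       588.31
      ],
      [
       576.29,
       689.36
      ],
      [
       576.29,
       852.42
      ]
     ]
    }
   ],
   "cMM": 59000.0,
   "u_MM": 340.0,
   "cCF": 0.5,
   "u_CF": 0.02
  },
  {
   "allergen_name": "Almond",
   "parent_protein_accessions": [
    "E3SH28"
   ],
   "markers": [
    {
     "code": "a-TEE",
     "sequence": "TEENAFINTLAGR",
     "role": "QTM",
     "label_shift": 10.0,
     "transitions": [
      [
       718.36,
       416.26
      ],
      [
       718.36,
       517.31
      ],
      [
       718.36,
       631.35
      ],
      [
       718.36,
       744.44
      ]
     ]
    },
    {
     "code": "a-ADIF",
     "sequence": "ADIFSPR",
     "role": "QLM",
     "label_shift": 10.0,
     "transitions": [
      [
       403.21,
       506.27
      ],
      [
       403.21,
       619.36
      ],
      [
       403.21,
       734.38
      ]
     ]
    }
   ],
   "cMM": 63000.0,
   "u_MM": 360.0,
   "cCF": 0.65,
   "u_CF": 0.02
  }
 ],
 "stock_rel_uncertainty": 0.3
}
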