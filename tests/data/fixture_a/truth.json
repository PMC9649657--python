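{
 "seed": 7,
 "contacts": [
  [
   1,
   "CB",
   2,
   "CD",
   6.4258
  ],
  [
   1,
   "CB",
   4,
   "CD",
   5.6377
  ],
  [
   5,
   "C",
   6,
   "C",
   3.0041
  ],
  [
   5,
   "C",
   7,
   "CG",
   5.7917
  ],
  [
   5,
   "C",
   8,
   "C",
   4.9534
  ],
  [
   5,
   "C",
   9,
   "C",
   6.2477
  ],
  [
   5,
   "C",
   9,
   "CD",
   4.4152
  ],
  [
   6,
   "C",
   7,
   "CG",
   4.2338
  ],
  [
   6,
   "C",
   8,
   "C",
   4.5545
  ],
  [
   6,
   "C",
   9,
   "C",
   4.9534
  ],
  [
   6,
   "C",
   9,
   "CD",
   5.1368
  ],
  [
   6,
   "C",
   10,
   "C",
   6.2477
  ],
  [
   6,
   "C",
   10,
   "CD",
   4.4152
  ],
  [
   7,
   "CG",
   8,
   "C",
   6.8258
  ],
  [
   7,
   "CG",
   10,
   "CD",
   5.741
  ],
  [
   7,
   "CG",
   17,
   "CG",
   6.2978
  ],
  [
   8,
   "C",
   9,
   "C",
   3.0041
  ],
  [
   8,
   "C",
   9,
   "CD",
   5.6921
  ],
  [
   8,
   "C",
   10,
   "C",
   4.5545
  ],
  [
   8,
   "C",
   10,
   "CD",
   6.866
  ],
  [
   8,
   "C",
   11,
   "CB",
   4.3231
  ],
  [
   8,
   "C",
   12,
   "CD",
   4.4152
  ],
  [
   8,
   "C",
   20,
   "CD",
   6.4615
  ],
  [
   9,
   "C",
   9,
   "CD",
   5.0692
  ],
  [
   9,
   "C",
   10,
   "C",
   3.0041
  ],
  [
   9,
   "C",
   10,
   "CD",
   5.6921
  ],
  [
   9,
   "C",
   11,
   "CB",
   5.1848
  ],
  [
   9,
   "C",
   12,
   "CD",
   5.1368
  ],
  [
   9,
   "C",
   13,
   "CD",
   4.4152
  ],
  [
   9,
   "C",
   20,
   "CD",
   6.2205
  ],
  [
   9,
   "CD",
   12,
   "CD",
   7.115
  ],
  [
   9,
   "CD",
   13,
   "CD",
   6.9141
  ],
  [
   10,
   "C",
   10,
   "CD",
   5.0692
  ],
  [
   10,
   "C",
   11,
   "CB",
   3.7172
  ],
  [
   10,
   "C",
   12,
   "CD",
   6.866
  ],
  [
   10,
   "C",
   13,
   "CD",
   5.1368
  ],
  [
   10,
   "C",
   15,
   "C",
   5.8505
  ],
  [
   10,
   "C",
   16,
   "C",
   6.3062
  ],
  [
   10,
   "C",
   17,
   "CG",
   5.8903
  ],
  [
   10,
   "C",
   20,
   "CD",
   3.5691
  ],
  [
   10,
   "CD",
   13,
   "CD",
   7.115
  ],
  [
   10,
   "CD",
   16,
   "C",
   6.2128
  ],
  [
   10,
   "CD",
   17,
   "CG",
   4.6085
  ],
  [
   10,
   "CD",
   20,
   "CD",
   5.6139
  ],
  [
   11,
   "CB",
   12,
   "CD",
   6.4258
  ],
  [
   11,
   "CB",
   17,
   "CG",
   6.5386
  ],
  [
   11,
   "CB",
   19,
   "C",
   6.8624
  ],
  [
   11,
   "CB",
   20,
   "C",
   6.2752
  ],
  [
   11,
   "CB",
   20,
   "CD",
   3.5275
  ],
  [
   11,
   "CB",
   23,
   "CD",
   5.8501
  ],
  [
   14,
   "CD",
   24,
   "CD",
   5.4434
  ],
  [
   15,
   "C",
   16,
   "C",
   3.3453
  ],
  [
   15,
   "C",
   17,
   "CG",
   5.877
  ],
  [
   15,
   "C",
   20,
   "C",
   6.8734
  ],
  [
   15,
   "C",
   20,
   "CD",
   5.1626
  ],
  [
   15,
   "C",
   21,
   "CB",
   7.0241
  ],
  [
   15,
   "C",
   24,
   "CD",
   6.2921
  ],
  [
   16,
   "C",
   17,
   "CG",
   3.0453
  ],
  [
   16,
   "C",
   18,
   "C",
   6.2056
  ],
  [
   16,
   "C",
   19,
   "C",
   6.8314
  ],
  [
   16,
   "C",
   20,
   "C",
   6.0302
  ],
  [
   16,
   "C",
   20,
   "CD",
   3.9906
  ],
  [
   16,
   "C",
   21,
   "CB",
   6.2082
  ],
  [
   17,
   "CG",
   18,
   "C",
   6.3465
  ],
  [
   17,
   "CG",
   19,
   "C",
   6.507
  ],
  [
   17,
   "CG",
   20,
   "C",
   6.8362
  ],
  [
   17,
   "CG",
   20,
   "CD",
   3.3439
  ],
  [
   18,
   "C",
   19,
   "C",
   3.0041
  ],
  [
   18,
   "C",
   19,
   "CD",
   5.6921
  ],
  [
   18,
   "C",
   20,
   "C",
   4.5545
  ],
  [
   18,
   "C",
   20,
   "CD",
   6.866
  ],
  [
   18,
   "C",
   21,
   "CB",
   4.3231
  ],
  [
   18,
   "C",
   22,
   "CD",
   4.4152
  ],
  [
   19,
   "C",
   19,
   "CD",
   5.0692
  ],
  [
   19,
   "C",
   20,
   "C",
   3.0041
  ],
  [
   19,
   "C",
   20,
   "CD",
   5.6921
  ],
  [
   19,
   "C",
   21,
   "CB",
   5.1848
  ],
  [
   19,
   "C",
   22,
   "CD",
   5.1368
  ],
  [
   19,
   "C",
   23,
   "CD",
   4.4152
  ],
  [
   19,
   "CD",
   22,
   "CD",
   7.115
  ],
  [
   19,
   "CD",
   23,
   "CD",
   6.9141
  ],
  [
   20,
   "C",
   20,
   "CD",
   5.0692
  ],
  [
   20,
   "C",
   21,
   "CB",
   3.7172
  ],
  [
   20,
   "C",
   22,
   "CD",
   6.866
  ],
  [
   20,
   "C",
   23,
   "CD",
   5.1368
  ],
  [
   20,
   "C",
   24,
   "CD",
   4.4152
  ],
  [
   20,
   "CD",
   23,
   "CD",
   7.115
  ],
  [
   20,
   "CD",
   24,
   "CD",
   6.9141
  ],
  [
   21,
   "CB",
   22,
   "CD",
   6.4258
  ],
  [
   21,
   "CB",
   24,
   "CD",
   5.6377
  ],
  [
   25,
   "C",
   26,
   "C",
   3.0041
  ],
  [
   25,
   "C",
   27,
   "CG",
   5.7917
  ],
  [
   25,
   "C",
   28,
   "C",
   4.9534
  ],
  [
   25,
   "C",
   29,
   "C",
   6.2477
  ],
  [
   25,
   "C",
   29,
   "CD",
   4.4152
  ],
  [
   26,
   "C",
   27,
   "CG",
   4.2338
  ],
  [
   26,
   "C",
   28,
   "C",
   4.5545
  ],
  [
   26,
   "C",
   29,
   "C",
   4.9534
  ],
  [
   26,
   "C",
   29,
   "CD",
   5.1368
  ],
  [
   26,
   "C",
   30,
   "C",
   6.2477
  ],
  [
   26,
   "C",
   30,
   "CD",
   4.4152
  ],
  [
   27,
   "CG",
   28,
   "C",
   6.8258
  ],
  [
   27,
   "CG",
   30,
   "CD",
   5.741
  ],
  [
   28,
   "C",
   29,
   "C",
   3.0041
  ],
  [
   28,
   "C",
   29,
   "CD",
   5.6921
  ],
  [
   28,
   "C",
   30,
   "C",
   4.5545
  ],
  [
   28,
   "C",
   30,
   "CD",
   6.866
  ],
  [
   29,
   "C",
   29,
   "CD",
   5.0692
  ],
  [
   29,
   "C",
   30,
   "C",
   3.0041
  ],
  [
   29,
   "C",
   30,
   "CD",
   5.6921
  ],
  [
   30,
   "C",
   30,
   "CD",
   5.0692
  ]
 ],
 "perturbed_residues": [],
 "placements": [
  {
   "rotation": [
    [
     1.0,
     -0.0,
     0.0
    ],
    [
     0.0,
     1.0,
     0.0
    ],
    [
     0.0,
     0.0,
     1.0
    ]
   ],
   "translation": [
    20.710512,
    -15.398003,
    0.435381
   ]
  },
  {
   "rotation": [
    [
     0.0,
     -1.0,
     0.0
    ],
    [
     1.0,
     0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     1.0
    ]
   ],
   "translation": [
    15.398003,
    20.710512,
    12.435381
   ]
  },
  {
   "rotation": [
    [
     -1.0,
     -0.0,
     0.0
    ],
    [
     0.0,
     -1.0,
     0.0
    ],
    [
     0.0,
     0.0,
     1.0
    ]
   ],
   "translation": [
    -20.710512,
    15.398003,
    24.435381
   ]
  },
  {
   "rotation": [
    [
     -0.0,
     1.0,
     0.0
    ],
    [
     -1.0,
     -0.0,
     0.0
    ],
    [
     0.0,
     0.0,
     1.0
    ]
   ],
   "translation": [
    -15.398003,
    -20.710512,
    36.435381
   ]
  }
 ]
}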