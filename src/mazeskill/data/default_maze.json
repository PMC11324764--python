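{
 "_comment": "Representative 21-section reconstruction: published outer size 170x150 mm, two alternative paths (upper corridor y in [100,150], lower corridor y in [0,50]) around a central block in the middle row, and one pit on each path. The interior wall placement is an artifact choice; only the outer dimensions, section count, two-path topology and pits-on-both-paths are published.",
 "width_mm": 170.0,
 "height_mm": 150.0,
 "walls": [
  [
   0.0,
   0.0,
   170.0,
   0.0
  ],
  [
   170.0,
   0.0,
   170.0,
   150.0
  ],
  [
   170.0,
   150.0,
   0.0,
   150.0
  ],
  [
   0.0,
   150.0,
   0.0,
   0.0
  ],
  [
   34.0,
   100.0,
   85.0,
   100.0
  ],
  [
   85.0,
   100.0,
   136.0,
   100.0
  ],
  [
   34.0,
   50.0,
   85.0,
   50.0
  ],
  [
   85.0,
   50.0,
   136.0,
   50.0
  ],
  [
   85.0,
   50.0,
   85.0,
   100.0
  ]
 ],
 "pits": [
  {
   "cx": 50.0,
   "cy": 138.0,
   "r": 8.0
  },
  {
   "cx": 120.0,
   "cy": 12.0,
   "r": 8.0
  }
 ],
 "sections": [
  {
   "id": 1,
   "polygon": [
    [
     0.0,
     0.0
    ],
    [
     24.285714,
     0.0
    ],
    [
     24.285714,
     50.0
    ],
    [
     0.0,
     50.0
    ]
   ],
   "adjacent": [
    2,
    8
   ]
  },
  {
   "id": 2,
   "polygon": [
    [
     24.285714,
     0.0
    ],
    [
     48.571429,
     0.0
    ],
    [
     48.571429,
     50.0
    ],
    [
     24.285714,
     50.0
    ]
   ],
   "adjacent": [
    1,
    3,
    9
   ]
  },
  {
   "id": 3,
   "polygon": [
    [
     48.571429,
     0.0
    ],
    [
     72.857143,
     0.0
    ],
    [
     72.857143,
     50.0
    ],
    [
     48.571429,
     50.0
    ]
   ],
   "adjacent": [
    2,
    4,
    10
   ]
  },
  {
   "id": 4,
   "polygon": [
    [
     72.857143,
     0.0
    ],
    [
     97.142857,
     0.0
    ],
    [
     97.142857,
     50.0
    ],
    [
     72.857143,
     50.0
    ]
   ],
   "adjacent": [
    3,
    5,
    11
   ]
  },
  {
   "id": 5,
   "polygon": [
    [
     97.142857,
     0.0
    ],
    [
     121.428571,
     0.0
    ],
    [
     121.428571,
     50.0
    ],
    [
     97.142857,
     50.0
    ]
   ],
   "adjacent": [
    4,
    6,
    12
   ]
  },
  {
   "id": 6,
   "polygon": [
    [
     121.428571,
     0.0
    ],
    [
     145.714286,
     0.0
    ],
    [
     145.714286,
     50.0
    ],
    [
     121.428571,
     50.0
    ]
   ],
   "adjacent": [
    5,
    7,
    13
   ]
  },
  {
   "id": 7,
   "polygon": [
    [
     145.714286,
     0.0
    ],
    [
     170.0,
     0.0
    ],
    [
     170.0,
     50.0
    ],
    [
     145.714286,
     50.0
    ]
   ],
   "adjacent": [
    6,
    14
   ]
  },
  {
   "id": 8,
   "polygon": [
    [
     0.0,
     50.0
    ],
    [
     24.285714,
     50.0
    ],
    [
     24.285714,
     100.0
    ],
    [
     0.0,
     100.0
    ]
   ],
   "adjacent": [
    1,
    9,
    15
   ]
  },
  {
   "id": 9,
   "polygon": [
    [
     24.285714,
     50.0
    ],
    [
     48.571429,
     50.0
    ],
    [
     48.571429,
     100.0
    ],
    [
     24.285714,
     100.0
    ]
   ],
   "adjacent": [
    2,
    8,
    10,
    16
   ]
  },
  {
   "id": 10,
   "polygon": [
    [
     48.571429,
     50.0
    ],
    [
     72.857143,
     50.0
    ],
    [
     72.857143,
     100.0
    ],
    [
     48.571429,
     100.0
    ]
   ],
   "adjacent": [
    3,
    9,
    11,
    17
   ]
  },
  {
   "id": 11,
   "polygon": [
    [
     72.857143,
     50.0
    ],
    [
     97.142857,
     50.0
    ],
    [
     97.142857,
     100.0
    ],
    [
     72.857143,
     100.0
    ]
   ],
   "adjacent": [
    4,
    10,
    12,
    18
   ]
  },
  {
   "id": 12,
   "polygon": [
    [
     97.142857,
     50.0
    ],
    [
     121.428571,
     50.0
    ],
    [
     121.428571,
     100.0
    ],
    [
     97.142857,
     100.0
    ]
   ],
   "adjacent": [
    5,
    11,
    13,
    19
   ]
  },
  {
   "id": 13,
   "polygon": [
    [
     121.428571,
     50.0
    ],
    [
     145.714286,
     50.0
    ],
    [
     145.714286,
     100.0
    ],
    [
     121.428571,
     100.0
    ]
   ],
   "adjacent": [
    6,
    12,
    14,
    20
   ]
  },
  {
   "id": 14,
   "polygon": [
    [
     145.714286,
     50.0
    ],
    [
     170.0,
     50.0
    ],
    [
     170.0,
     100.0
    ],
    [
     145.714286,
     100.0
    ]
   ],
   "adjacent": [
    7,
    13,
    21
   ]
  },
  {
   "id": 15,
   "polygon": [
    [
     0.0,
     100.0
    ],
    [
     24.285714,
     100.0
    ],
    [
     24.285714,
     150.0
    ],
    [
     0.0,
     150.0
    ]
   ],
   "adjacent": [
    8,
    16
   ]
  },
  {
   "id": 16,
   "polygon": [
    [
     24.285714,
     100.0
    ],
    [
     48.571429,
     100.0
    ],
    [
     48.571429,
     150.0
    ],
    [
     24.285714,
     150.0
    ]
   ],
   "adjacent": [
    9,
    15,
    17
   ]
  },
  {
   "id": 17,
   "polygon": [
    [
     48.571429,
     100.0
    ],
    [
     72.857143,
     100.0
    ],
    [
     72.857143,
     150.0
    ],
    [
     48.571429,
     150.0
    ]
   ],
   "adjacent": [
    10,
    16,
    18
   ]
  },
  {
   "id": 18,
   "polygon": [
    [
     72.857143,
     100.0
    ],
    [
     97.142857,
     100.0
    ],
    [
     97.142857,
     150.0
    ],
    [
     72.857143,
     150.0
    ]
   ],
   "adjacent": [
    11,
    17,
    19
   ]
  },
  {
   "id": 19,
   "polygon": [
    [
     97.142857,
     100.0
    ],
    [
     121.428571,
     100.0
    ],
    [
     121.428571,
     150.0
    ],
    [
     97.142857,
     150.0
    ]
   ],
   "adjacent": [
    12,
    18,
    20
   ]
  },
  {
   "id": 20,
   "polygon": [
    [
     121.428571,
     100.0
    ],
    [
     145.714286,
     100.0
    ],
    [
     145.714286,
     150.0
    ],
    [
     121.428571,
     150.0
    ]
   ],
   "adjacent": [
    13,
    19,
    21
   ]
  },
  {
   "id": 21,
   "polygon": [
    [
     145.714286,
     100.0
    ],
    [
     170.0,
     100.0
    ],
    [
     170.0,
     150.0
    ],
    [
     145.714286,
     150.0
    ]
   ],
   "adjacent": [
    14,
    20
   ]
  }
 ],
 "start": [
  12.0,
  75.0
 ],
 "target": [
  158.0,
  75.0
 ],
 "sphere_radius_mm": 7.5
}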