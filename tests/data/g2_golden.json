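{
  "dialect": "alphafold3",
  "version": 2,
  "name": "g2",
  "modelSeeds": [
    1
  ],
  "sequences": [
    {
      "ligand": {
        "id": "NG",
        "ccdCodes": [
          "NAG",
          "NAG",
          "BMA",
          "MAN",
          "MAN",
          "NAG",
          "NAG",
          "GAL",
          "GAL"
        ]
      }
    }
  ],
  "bondedAtomPairs": [
    [
      [
        "NG",
        1,
        "O4"
      ],
      [
        "NG",
        2,
        "C1"
      ]
    ],
    [
      [
        "NG",
        2,
        "O4"
      ],
      [
        "NG",
        3,
        "C1"
      ]
    ],
    [
      [
        "NG",
        3,
        "O3"
      ],
      [
        "NG",
        4,
        "C1"
      ]
    ],
    [
      [
        "NG",
        3,
        "O6"
      ],
      [
        "NG",
        5,
        "C1"
      ]
    ],
    [
      [
        "NG",
        4,
        "O2"
      ],
      [
        "NG",
        6,
        "C1"
      ]
    ],
    [
      [
        "NG",
        5,
        "O2"
      ],
      [
        "NG",
        7,
        "C1"
      ]
    ],
    [
      [
        "NG",
        6,
        "O4"
      ],
      [
        "NG",
        8,
        "C1"
      ]
    ],
    [
      [
        "NG",
        7,
        "O4"
      ],
      [
        "NG",
        9,
        "C1"
      ]
    ]
  ]
}
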