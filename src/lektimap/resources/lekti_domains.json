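{
  "protein": "LEKTI",
  "domains": [
    {"index": 1, "aa_start": 28, "aa_end": 66},
    {"index": 2, "aa_start": 91, "aa_end": 153},
    {"index": 3, "aa_start": 155, "aa_end": 216},
    {"index": 4, "aa_start": 219, "aa_end": 285},
    {"index": 5, "aa_start": 291, "aa_end": 352},
    {"index": 6, "aa_start": 361, "aa_end": 423},
    {"index": 7, "aa_start": 431, "aa_end": 489},
    {"index": 8, "aa_start": 490, "aa_end": 551},
    {"index": 9, "aa_start": 561, "aa_end": 622},
    {"index": 10, "aa_start": 626, "aa_end": 688},
    {"index": 11, "aa_start": 701, "aa_end": 757},
    {"index": 12, "aa_start": 768, "aa_end": 830},
    {"index": 13, "aa_start": 843, "aa_end": 905},
    {"index": 14, "aa_start": 910, "aa_end": 971},
    {"index": 15, "aa_start": 987, "aa_end": 1048}
  ],
  "regions": [
    {"index": 1, "member_domains": [1, 2, 3, 4, 5]},
    {"index": 2, "member_domains": [6]},
    {"index": 3, "member_domains": [7]},
    {"index": 4, "member_domains": [8, 9]},
    {"index": 5, "member_domains": [10, 11, 12, 13, 14, 15]}
  ]
}
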