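cells:
- age_lo: 0.0
  age_hi: 5.0
  verbal_level: some_words
  map:
    0: 1
    1: 1
    2: 1
    3: 2
    4: 2
    5: 2
    6: 3
    7: 3
    8: 3
    9: 4
    10: 4
    11: 4
    12: 5
    13: 5
    14: 5
    15: 6
    16: 6
    17: 6
    18: 7
    19: 7
    20: 7
    21: 8
    22: 8
    23: 8
    24: 9
    25: 9
    26: 9
    27: 10
    28: 10
- age_lo: 5.0
  age_hi: 21.0
  verbal_level: some_words
  map:
    0: 1
    1: 1
    2: 1
    3: 2
    4: 2
    5: 2
    6: 3
    7: 3
    8: 3
    9: 4
    10: 4
    11: 4
    12: 5
    13: 5
    14: 5
    15: 6
    16: 6
    17: 6
    18: 7
    19: 7
    20: 7
    21: 8
    22: 8
    23: 8
    24: 9
    25: 9
    26: 9
    27: 10
    28: 10
- age_lo: 0.0
  age_hi: 5.0
  verbal_level: few_to_no_words
  map:
    0: 1
    1: 1
    2: 1
    3: 2
    4: 2
    5: 2
    6: 3
    7: 3
    8: 3
    9: 4
    10: 4
    11: 4
    12: 5
    13: 5
    14: 5
    15: 6
    16: 6
    17: 6
    18: 7
    19: 7
    20: 7
    21: 8
    22: 8
    23: 8
    24: 9
    25: 9
    26: 9
    27: 10
    28: 10
- age_lo: 5.0
  age_hi: 21.0
  verbal_level: few_to_no_words
  map:
    0: 1
    1: 1
    2: 1
    3: 2
    4: 2
    5: 2
    6: 3
    7: 3
    8: 3
    9: 4
    10: 4
    11: 4
    12: 5
    13: 5
    14: 5
    15: 6
    16: 6
    17: 6
    18: 7
    19: 7
    20: 7
    21: 8
    22: 8
    23: 8
    24: 9
    25: 9
    26: 9
    27: 10
    28: 10
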