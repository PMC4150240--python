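ados2_autism_cutoff:
  few_to_no_words: 16
  some_words: 12
ados2_rrb_items:
  few_to_no_words:
  - A3
  - D1
  - D2
  - D4
  some_words:
  - A3
  - D1
  - D2
  - D4
ados2_sa_items:
  few_to_no_words:
  - A2
  - A4
  - A8
  - B1
  - B2
  - B3
  - B5
  - B9
  - B10
  - B12
  some_words:
  - A2
  - A7
  - A8
  - B1
  - B2
  - B5
  - B9
  - B10
  - B11
  - B12
ados2_spectrum_cutoff:
  few_to_no_words: 11
  some_words: 8
adosg_autism_cutoffs:
  comm: 4
  social: 7
  total: 12
adosg_comm_items:
- A2
- A5
- A7
- A8
adosg_social_items:
- B1
- B2
- B5
- B8
- B9
- B10
- B11
adosg_spectrum_cutoffs:
  comm: 2
  social: 4
  total: 7
borderline_margin: 1
class_sign: -1
fewno_words_min_code: 3
low_confidence_threshold: 2.0
obc_features:
- - frequency of vocalization directed to others
  - A2
- - eye contact
  - B1
- - social smile
  - B2
- - shared enjoyment in interaction
  - B5
- - showing
  - B9
- - initiation of joint attention
  - B10
- - functional play with objects
  - C1
- - imagination/creativity
  - C2
special_code_recode:
  7: 0
  8: 0
three_recode:
  3: 2
verbal_item: A1
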