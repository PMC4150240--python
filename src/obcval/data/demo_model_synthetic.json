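{
 "class_sign": -1,
 "features": [
  [
   "frequency of vocalization directed to others",
   "A2"
  ],
  [
   "eye contact",
   "B1"
  ],
  [
   "social smile",
   "B2"
  ],
  [
   "shared enjoyment in interaction",
   "B5"
  ],
  [
   "showing",
   "B9"
  ],
  [
   "initiation of joint attention",
   "B10"
  ],
  [
   "functional play with objects",
   "C1"
  ],
  [
   "imagination/creativity",
   "C2"
  ]
 ],
 "root_value": -1.0881551105936746,
 "rules": [
  {
   "item": "B1",
   "precondition": null,
   "threshold": 1,
   "value_false": 0.8578531352460597,
   "value_true": -0.6784247412623952
  },
  {
   "item": "A2",
   "precondition": null,
   "threshold": 2,
   "value_false": 0.5003174952822554,
   "value_true": -0.9559374050538245
  },
  {
   "item": "B10",
   "precondition": null,
   "threshold": 1,
   "value_false": 0.6401441646580532,
   "value_true": -0.5476046359378961
  },
  {
   "item": "B2",
   "precondition": null,
   "threshold": 1,
   "value_false": 0.5660951658534591,
   "value_true": -0.3901863594930806
  },
  {
   "item": "C2",
   "precondition": null,
   "threshold": 2,
   "value_false": 0.334463532832209,
   "value_true": -0.5192244169649959
  },
  {
   "item": "A2",
   "precondition": {
    "branch": true,
    "rule": 2
   },
   "threshold": 1,
   "value_false": 0.4918023081927466,
   "value_true": -0.5763513838369818
  },
  {
   "item": "B9",
   "precondition": {
    "branch": false,
    "rule": 0
   },
   "threshold": 2,
   "value_false": 0.1214380256855975,
   "value_true": -0.9065673736895853
  },
  {
   "item": "B5",
   "precondition": {
    "branch": true,
    "rule": 1
   },
   "threshold": 2,
   "value_false": 0.6408083435848264,
   "value_true": -1.2098996344312543
  }
 ],
 "train_loss": [
  0.46196990924394604,
  0.37021697232546,
  0.3130088480043519,
  0.2809803788514047,
  0.25795184403702764,
  0.2398574333892998,
  0.22363216656052962,
  0.20935099009499403
 ],
 "version": 1
}
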