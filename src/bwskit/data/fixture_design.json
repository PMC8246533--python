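{
 "version": 1,
 "v": 9,
 "b": 9,
 "k": 4,
 "item_labels": [
  "O1",
  "O2",
  "O3",
  "O4",
  "O5",
  "O6",
  "O7",
  "O8",
  "O9"
 ],
 "blocks": [
  [
   "O1",
   "O6",
   "O7",
   "O9"
  ],
  [
   "O4",
   "O5",
   "O8",
   "O9"
  ],
  [
   "O2",
   "O3",
   "O6",
   "O9"
  ],
  [
   "O1",
   "O4",
   "O5",
   "O6"
  ],
  [
   "O2",
   "O5",
   "O6",
   "O8"
  ],
  [
   "O1",
   "O2",
   "O4",
   "O7"
  ],
  [
   "O1",
   "O3",
   "O8",
   "O9"
  ],
  [
   "O2",
   "O3",
   "O5",
   "O7"
  ],
  [
   "O3",
   "O4",
   "O7",
   "O8"
  ]
 ]
}
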