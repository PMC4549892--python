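{
 "name": "geometric_ladder",
 "units": "kb",
 "bands": [
  {
   "label": "L01",
   "mw": 1000.0
  },
  {
   "label": "L02",
   "mw": 854.1315
  },
  {
   "label": "L03",
   "mw": 729.5406
  },
  {
   "label": "L04",
   "mw": 623.1236
  },
  {
   "label": "L05",
   "mw": 532.2295
  },
  {
   "label": "L06",
   "mw": 454.594
  },
  {
   "label": "L07",
   "mw": 388.283
  },
  {
   "label": "L08",
   "mw": 331.6448
  },
  {
   "label": "L09",
   "mw": 283.2682
  },
  {
   "label": "L10",
   "mw": 241.9483
  },
  {
   "label": "L11",
   "mw": 206.6557
  },
  {
   "label": "L12",
   "mw": 176.5111
  },
  {
   "label": "L13",
   "mw": 150.7637
  },
  {
   "label": "L14",
   "mw": 128.772
  },
  {
   "label": "L15",
   "mw": 109.9883
  },
  {
   "label": "L16",
   "mw": 93.9444
  },
  {
   "label": "L17",
   "mw": 80.2409
  },
  {
   "label": "L18",
   "mw": 68.5363
  },
  {
   "label": "L19",
   "mw": 58.539
  },
  {
   "label": "L20",
   "mw": 50.0
  }
 ]
}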