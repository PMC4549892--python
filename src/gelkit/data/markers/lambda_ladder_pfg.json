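{
 "name": "lambda_ladder_pfg",
 "units": "kb",
 "bands": [
  {
   "label": "21x48.5",
   "mw": 1018.5
  },
  {
   "label": "20x48.5",
   "mw": 970.0
  },
  {
   "label": "19x48.5",
   "mw": 921.5
  },
  {
   "label": "18x48.5",
   "mw": 873.0
  },
  {
   "label": "17x48.5",
   "mw": 824.5
  },
  {
   "label": "16x48.5",
   "mw": 776.0
  },
  {
   "label": "15x48.5",
   "mw": 727.5
  },
  {
   "label": "14x48.5",
   "mw": 679.0
  },
  {
   "label": "13x48.5",
   "mw": 630.5
  },
  {
   "label": "12x48.5",
   "mw": 582.0
  },
  {
   "label": "11x48.5",
   "mw": 533.5
  },
  {
   "label": "10x48.5",
   "mw": 485.0
  },
  {
   "label": "9x48.5",
   "mw": 436.5
  },
  {
   "label": "8x48.5",
   "mw": 388.0
  },
  {
   "label": "7x48.5",
   "mw": 339.5
  },
  {
   "label": "6x48.5",
   "mw": 291.0
  },
  {
   "label": "5x48.5",
   "mw": 242.5
  },
  {
   "label": "4x48.5",
   "mw": 194.0
  },
  {
   "label": "3x48.5",
   "mw": 145.5
  },
  {
   "label": "2x48.5",
   "mw": 97.0
  },
  {
   "label": "1x48.5",
   "mw": 48.5
  }
 ]
}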