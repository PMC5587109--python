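{
 "note": "Synthetic reconstruction of the six-bar Alouette excerpt used in the copy-composing task. The true note-by-note content is not published; this fixture is calibrated so that the grammar's minimum selection count (Compose + entries + play all) equals the documented 41 selections.",
 "time_signature": "4/4",
 "notes": [
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "eighth",
   "dotted": false
  },
  {
   "pitch": "A",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  },
  {
   "pitch": "G",
   "octave": 4,
   "length": "half",
   "dotted": true
  },
  {
   "pitch": "F",
   "octave": 4,
   "length": "quarter",
   "dotted": false
  }
 ]
}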