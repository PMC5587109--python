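{
 "note": "26-item user experience questionnaire: item-to-subscale map and polarity of the standard published instrument",
 "items": [
  {
   "index": 1,
   "poles": "annoying / enjoyable",
   "subscale": "attractiveness",
   "positive_pole": "right"
  },
  {
   "index": 2,
   "poles": "not understandable / understandable",
   "subscale": "perspicuity",
   "positive_pole": "right"
  },
  {
   "index": 3,
   "poles": "creative / dull",
   "subscale": "novelty",
   "positive_pole": "left"
  },
  {
   "index": 4,
   "poles": "easy to learn / difficult to learn",
   "subscale": "perspicuity",
   "positive_pole": "left"
  },
  {
   "index": 5,
   "poles": "valuable / inferior",
   "subscale": "stimulation",
   "positive_pole": "left"
  },
  {
   "index": 6,
   "poles": "boring / exciting",
   "subscale": "stimulation",
   "positive_pole": "right"
  },
  {
   "index": 7,
   "poles": "not interesting / interesting",
   "subscale": "stimulation",
   "positive_pole": "right"
  },
  {
   "index": 8,
   "poles": "unpredictable / predictable",
   "subscale": "dependability",
   "positive_pole": "right"
  },
  {
   "index": 9,
   "poles": "fast / slow",
   "subscale": "efficiency",
   "positive_pole": "left"
  },
  {
   "index": 10,
   "poles": "inventive / conventional",
   "subscale": "novelty",
   "positive_pole": "left"
  },
  {
   "index": 11,
   "poles": "obstructive / supportive",
   "subscale": "dependability",
   "positive_pole": "right"
  },
  {
   "index": 12,
   "poles": "good / bad",
   "subscale": "attractiveness",
   "positive_pole": "left"
  },
  {
   "index": 13,
   "poles": "complicated / easy",
   "subscale": "perspicuity",
   "positive_pole": "right"
  },
  {
   "index": 14,
   "poles": "unlikable / pleasing",
   "subscale": "attractiveness",
   "positive_pole": "right"
  },
  {
   "index": 15,
   "poles": "usual / leading edge",
   "subscale": "novelty",
   "positive_pole": "right"
  },
  {
   "index": 16,
   "poles": "unpleasant / pleasant",
   "subscale": "attractiveness",
   "positive_pole": "right"
  },
  {
   "index": 17,
   "poles": "secure / not secure",
   "subscale": "dependability",
   "positive_pole": "left"
  },
  {
   "index": 18,
   "poles": "motivating / demotivating",
   "subscale": "stimulation",
   "positive_pole": "left"
  },
  {
   "index": 19,
   "poles": "meets expectations / does not meet expectations",
   "subscale": "dependability",
   "positive_pole": "left"
  },
  {
   "index": 20,
   "poles": "inefficient / efficient",
   "subscale": "efficiency",
   "positive_pole": "right"
  },
  {
   "index": 21,
   "poles": "clear / confusing",
   "subscale": "perspicuity",
   "positive_pole": "left"
  },
  {
   "index": 22,
   "poles": "impractical / practical",
   "subscale": "efficiency",
   "positive_pole": "right"
  },
  {
   "index": 23,
   "poles": "organized / cluttered",
   "subscale": "efficiency",
   "positive_pole": "left"
  },
  {
   "index": 24,
   "poles": "attractive / unattractive",
   "subscale": "attractiveness",
   "positive_pole": "left"
  },
  {
   "index": 25,
   "poles": "friendly / unfriendly",
   "subscale": "attractiveness",
   "positive_pole": "left"
  },
  {
   "index": 26,
   "poles": "conservative / innovative",
   "subscale": "novelty",
   "positive_pole": "right"
  }
 ]
}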