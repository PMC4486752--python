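[
  {"word_en": "truth", "word_es": "verdad", "valence": "positive", "category": "logic"},
  {"word_en": "certainty", "word_es": "certeza", "valence": "positive", "category": "logic"},
  {"word_en": "consistency", "word_es": "consistencia", "valence": "positive", "category": "logic"},
  {"word_en": "exactness", "word_es": "exactitud", "valence": "positive", "category": "logic"},
  {"word_en": "adequacy", "word_es": "adecuación", "valence": "positive", "category": "logic"},
  {"word_en": "authenticity", "word_es": "autenticidad", "valence": "positive", "category": "logic"},
  {"word_en": "conformity", "word_es": "conformidad", "valence": "positive", "category": "logic"},
  {"word_en": "reality", "word_es": "realidad", "valence": "positive", "category": "logic"},
  {"word_en": "falsehood", "word_es": "falsedad", "valence": "negative", "category": "logic"},
  {"word_en": "inexactitude", "word_es": "inexactitud", "valence": "negative", "category": "logic"},
  {"word_en": "incorrectness", "word_es": "incorrección", "valence": "negative", "category": "logic"},
  {"word_en": "inadequacy", "word_es": "inadecuación", "valence": "negative", "category": "logic"},
  {"word_en": "error", "word_es": "error", "valence": "negative", "category": "logic"},
  {"word_en": "doubt", "word_es": "duda", "valence": "negative", "category": "logic"},
  {"word_en": "deception", "word_es": "engaño", "valence": "negative", "category": "logic"},
  {"word_en": "misrepresentation", "word_es": "tergiversación", "valence": "negative", "category": "logic"},
  {"word_en": "loyalty", "word_es": "lealtad", "valence": "positive", "category": "morality"},
  {"word_en": "goodness", "word_es": "bondad", "valence": "positive", "category": "morality"},
  {"word_en": "charity", "word_es": "caridad", "valence": "positive", "category": "morality"},
  {"word_en": "solidarity", "word_es": "solidaridad", "valence": "positive", "category": "morality"},
  {"word_en": "humility", "word_es": "humildad", "valence": "positive", "category": "morality"},
  {"word_en": "generosity", "word_es": "generosidad", "valence": "positive", "category": "morality"},
  {"word_en": "prudence", "word_es": "prudencia", "valence": "positive", "category": "morality"},
  {"word_en": "patience", "word_es": "paciencia", "valence": "positive", "category": "morality"},
  {"word_en": "lust", "word_es": "lujuria", "valence": "negative", "category": "morality"},
  {"word_en": "gluttony", "word_es": "gula", "valence": "negative", "category": "morality"},
  {"word_en": "laziness", "word_es": "pereza", "valence": "negative", "category": "morality"},
  {"word_en": "evil", "word_es": "maldad", "valence": "negative", "category": "morality"},
  {"word_en": "avarice", "word_es": "avaricia", "valence": "negative", "category": "morality"},
  {"word_en": "envy", "word_es": "envidia", "valence": "negative", "category": "morality"},
  {"word_en": "pride", "word_es": "vanidad", "valence": "negative", "category": "morality"},
  {"word_en": "anger", "word_es": "ira", "valence": "negative", "category": "morality"}
]
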