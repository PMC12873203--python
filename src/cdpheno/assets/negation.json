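{
  "comment": "NegEx/ConText-style trigger inventory for the rule-based assertion classifier.",
  "pre_triggers": [
    "no",
    "not",
    "without",
    "denies",
    "denied",
    "no evidence of",
    "without evidence of",
    "negative for",
    "free of",
    "absence of",
    "rules out",
    "ruled out"
  ],
  "post_triggers": [
    "was ruled out",
    "were ruled out",
    "is ruled out",
    "has been ruled out",
    "is not seen",
    "not identified",
    "not visualized"
  ],
  "scope_terminators": [
    "but",
    "however",
    "although",
    "though",
    "except",
    "aside from",
    "apart from"
  ],
  "max_scope_tokens": 6
}
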