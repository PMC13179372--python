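{
  "comment": "Ordered keyword rules mapping free-text acid-base narratives to the six harmonized categories. First matching rule wins. Every keyword in `require` must occur (case-insensitive, matched at a word start, so 'compensat' covers 'compensatory'/'compensated'/'compensation' while 'normal' does not match 'abnormal'). Compensation rules precede dual-disorder rules so that compensation language never creates a second disorder. `default` null means unmappable narratives raise instead of being silently binned.",
  "default": null,
  "rules": [
    {"require": ["mixed"], "target": "mixed"},
    {"require": ["combined"], "target": "mixed"},
    {"require": ["metabolic acidosis", "compensat"], "target": "metabolic_acidosis"},
    {"require": ["metabolic alkalosis", "compensat"], "target": "metabolic_alkalosis"},
    {"require": ["respiratory acidosis", "compensat"], "target": "respiratory_acidosis"},
    {"require": ["respiratory alkalosis", "compensat"], "target": "respiratory_alkalosis"},
    {"require": ["metabolic acidosis", "respiratory acidosis"], "target": "mixed"},
    {"require": ["metabolic acidosis", "respiratory alkalosis"], "target": "mixed"},
    {"require": ["metabolic alkalosis", "respiratory acidosis"], "target": "mixed"},
    {"require": ["metabolic alkalosis", "respiratory alkalosis"], "target": "mixed"},
    {"require": ["metabolic acidosis"], "target": "metabolic_acidosis"},
    {"require": ["metabolic alkalosis"], "target": "metabolic_alkalosis"},
    {"require": ["respiratory acidosis"], "target": "respiratory_acidosis"},
    {"require": ["respiratory alkalosis"], "target": "respiratory_alkalosis"},
    {"require": ["normal"], "target": "normal"},
    {"require": ["no acid"], "target": "normal"}
  ]
}
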