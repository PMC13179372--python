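"""Harmonize free-text diagnostic narratives onto the six categories.

Mapping is an ordered keyword rule table (first match wins), shipped as
editable JSON — deterministic and auditable, no language model involved.
"""

from abgeval import harmonize_interpretation

narratives = [
    "Combined metabolic acidosis and respiratory acidosis",
    "Metabolic acidosis with appropriate respiratory compensation",
    "Normal acid–base status",
    "Mixed picture: metabolic alkalosis superimposed on respiratory acidosis",
    "Compensated respiratory acidosis in a COPD patient",
]

for text in narratives:
    category = harmonize_interpretation(text)
    print(f"{category.value:<21} <- {text!r}")

print(
    "\ncompensation language never creates a second disorder; two primary "
    "disorders named outside compensation context map to 'mixed'"
)
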