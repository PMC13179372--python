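"""Deterministic keyword harmonization of free-text interpretations.

Evaluators express diagnoses as narratives ("metabolic acidosis with
appropriate respiratory compensation"); comparison requires collapsing
them onto the six harmonized categories. The mapping here is an ordered,
auditable keyword rule table — first match wins — not natural-language
understanding. The shipped table lives in ``data/harmonization_rules.json``
and is fully replaceable.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .categories import AcidBaseCategory


class UnmappableNarrativeError(ValueError):
    """Raised when no rule matches and the table configures no default."""


@dataclass(frozen=True)
class HarmonizationRule:
    """All keywords in ``require`` must occur for ``target`` to apply."""

    require: tuple[str, ...]
    target: AcidBaseCategory


@dataclass(frozen=True)
class HarmonizationRuleTable:
    rules: tuple[HarmonizationRule, ...]
    default: AcidBaseCategory | None = None

    @classmethod
    def from_dict(cls, payload: dict) -> "HarmonizationRuleTable":
        rules = tuple(
            HarmonizationRule(
                require=tuple(kw.lower() for kw in entry["require"]),
                target=AcidBaseCategory(entry["target"]),
            )
            for entry in payload["rules"]
        )
        default = payload.get("default")
        return cls(
            rules=rules,
            default=AcidBaseCategory(default) if default is not None else None,
        )

    @classmethod
    def from_json(cls, path) -> "HarmonizationRuleTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_rule_table() -> HarmonizationRuleTable:
    """The rule table versioned with the package."""
    payload = json.loads(
        resources.files("abgeval.data")
        .joinpath("harmonization_rules.json")
        .read_text(encoding="utf-8")
    )
    return HarmonizationRuleTable.from_dict(payload)


def _normalize(text: str) -> str:
    # fold unicode dashes etc. so "acid–base" == "acid-base"
    text = unicodedata.normalize("NFKD", text)
    text = text.replace("–", "-").replace("—", "-")
    return text.lower()


def _keyword_present(keyword: str, text: str) -> bool:
    # match at a word start, allow stem continuation: "compensat" hits
    # "compensatory" but "normal" does not hit "abnormal"
    parts = [re.escape(p) for p in keyword.split()]
    pattern = r"\b" + r"\s+".join(parts)
    return re.search(pattern, text) is not None


def harmonize_interpretation(
    text: str, rules: HarmonizationRuleTable | None = None
) -> AcidBaseCategory:
    """Map a free-text diagnostic narrative to one harmonized category.

    Deterministic for a fixed table: rules are tried in order and the first
    whose keywords all occur wins. Raises :class:`UnmappableNarrativeError`
    when nothing matches and the table has no default.
    """
    if not text or not text.strip():
        raise ValueError("narrative text must be non-empty")
    table = rules if rules is not None else default_rule_table()
    normalized = _normalize(text)
    for rule in table.rules:
        if all(_keyword_present(kw, normalized) for kw in rule.require):
            return rule.target
    if table.default is not None:
        return table.default
    raise UnmappableNarrativeError(
        f"no harmonization rule matches narrative: {text!r}"
    )


def harmonize_many(
    texts: Sequence[str], rules: HarmonizationRuleTable | None = None
) -> list[AcidBaseCategory]:
    table = rules if rules is not None else default_rule_table()
    return [harmonize_interpretation(t, table) for t in texts]
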