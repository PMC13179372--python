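"""Cohort containers: per-case records and the dataset every metric consumes."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .categories import AcidBaseCategory, ComponentProfile, derive_components


@dataclass(frozen=True)
class Assessment:
    """One evaluator's read of one case.

    ``predicted_components`` may differ from what ``predicted_category``
    implies: component presence is coded independently from the free-text
    narrative (a narrative may name a second disturbance as "compensation"
    while the categorical call stays single).
    """

    predicted_category: AcidBaseCategory
    predicted_components: ComponentProfile

    @classmethod
    def from_category(cls, category: AcidBaseCategory) -> "Assessment":
        """Build an assessment whose components follow from the category."""
        return cls(category, derive_components(category))


@dataclass(frozen=True)
class CaseRecord:
    """One patient case: reference diagnosis plus each evaluator's assessment."""

    case_id: str
    reference_category: AcidBaseCategory
    reference_components: ComponentProfile
    assessments: dict[str, Assessment] = field(default_factory=dict)

    def assessment(self, evaluator: str) -> Assessment:
        try:
            return self.assessments[evaluator]
        except KeyError:
            raise KeyError(
                f"evaluator {evaluator!r} has no assessment for case {self.case_id!r}"
            ) from None


@dataclass
class CohortDataset:
    """Ordered collection of cases with an evaluator roster.

    Invariants checked at construction: unique case ids, at least one case,
    and every evaluator on the roster assessing every case exactly once.
    """

    cases: list[CaseRecord]
    evaluators: list[str]
    provenance: str = "user"

    def __post_init__(self) -> None:
        if not self.cases:
            raise ValueError("cohort must contain at least one case")
        ids = [c.case_id for c in self.cases]
        dupes = [cid for cid, k in Counter(ids).items() if k > 1]
        if dupes:
            raise ValueError(f"duplicate case ids: {dupes}")
        for case in self.cases:
            missing = [e for e in self.evaluators if e not in case.assessments]
            if missing:
                raise ValueError(
                    f"case {case.case_id!r} lacks assessments for {missing}"
                )

    @property
    def n(self) -> int:
        return len(self.cases)

    def require_evaluator(self, evaluator: str) -> None:
        if evaluator not in self.evaluators:
            raise KeyError(
                f"unknown evaluator {evaluator!r}; roster is {self.evaluators}"
            )

    def reference_counts(self) -> dict[AcidBaseCategory, int]:
        counts: Counter[AcidBaseCategory] = Counter(
            c.reference_category for c in self.cases
        )
        return {cat: counts.get(cat, 0) for cat in AcidBaseCategory}


def make_case(
    case_id: str,
    reference: AcidBaseCategory,
    assessments: dict[str, Assessment | AcidBaseCategory],
) -> CaseRecord:
    """Convenience constructor: reference components derived from the
    reference category; bare categories promoted to derived-component
    assessments."""
    norm = {
        e: (a if isinstance(a, Assessment) else Assessment.from_category(a))
        for e, a in assessments.items()
    }
    return CaseRecord(
        case_id=case_id,
        reference_category=reference,
        reference_components=derive_components(reference),
        assessments=norm,
    )
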