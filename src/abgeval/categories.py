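"""Diagnostic category vocabulary and error taxonomy.

Acid-base interpretations are harmonized into six exclusive categories:
normal status, the four single (primary) disorders, and mixed disorders
(simultaneous metabolic and respiratory disturbance). Misclassifications
are graded into a three-tier severity taxonomy whose apex is *false
reassurance*: calling a mixed disorder normal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class AcidBaseCategory(str, enum.Enum):
    """The six harmonized diagnostic categories."""

    NORMAL = "normal"
    METABOLIC_ACIDOSIS = "metabolic_acidosis"
    METABOLIC_ALKALOSIS = "metabolic_alkalosis"
    RESPIRATORY_ACIDOSIS = "respiratory_acidosis"
    RESPIRATORY_ALKALOSIS = "respiratory_alkalosis"
    MIXED = "mixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed category order used for confusion-matrix rows/columns in reports
#: (most complex first, then by descending cohort prevalence).
CATEGORY_ORDER: tuple[AcidBaseCategory, ...] = (
    AcidBaseCategory.MIXED,
    AcidBaseCategory.METABOLIC_ALKALOSIS,
    AcidBaseCategory.RESPIRATORY_ALKALOSIS,
    AcidBaseCategory.NORMAL,
    AcidBaseCategory.RESPIRATORY_ACIDOSIS,
    AcidBaseCategory.METABOLIC_ACIDOSIS,
)

_SINGLE_METABOLIC = frozenset(
    {AcidBaseCategory.METABOLIC_ACIDOSIS, AcidBaseCategory.METABOLIC_ALKALOSIS}
)
_SINGLE_RESPIRATORY = frozenset(
    {AcidBaseCategory.RESPIRATORY_ACIDOSIS, AcidBaseCategory.RESPIRATORY_ALKALOSIS}
)
SINGLE_DISORDERS: frozenset[AcidBaseCategory] = _SINGLE_METABOLIC | _SINGLE_RESPIRATORY


@dataclass(frozen=True)
class ComponentProfile:
    """Multi-label decomposition of a diagnosis into its physiological axes.

    A mixed disorder carries both components; a single (primary) disorder
    exactly one; normal status neither.
    """

    metabolic: bool
    respiratory: bool

    def as_tuple(self) -> tuple[bool, bool]:
        return (self.metabolic, self.respiratory)


class ErrorType(str, enum.Enum):
    """Severity taxonomy for categorical misclassification.

    ``FALSE_REASSURANCE`` (a mixed disorder read as normal) outranks
    ``MIXED_AS_SINGLE`` (a mixed disorder reduced to one primary disorder),
    which outranks every remaining disagreement. Overclassification of a
    single/normal case as mixed falls in the residual tier.
    """

    CORRECT = "correct"
    FALSE_REASSURANCE = "false_reassurance"
    MIXED_AS_SINGLE = "mixed_as_single"
    OTHER_MISCLASSIFICATION = "other_misclassification"


def derive_components(category: AcidBaseCategory) -> ComponentProfile:
    """Map a diagnostic category to its implied component profile.

    normal -> (False, False); single metabolic disorders -> (True, False);
    single respiratory disorders -> (False, True); mixed -> (True, True).
    """
    return ComponentProfile(
        metabolic=category is AcidBaseCategory.MIXED or category in _SINGLE_METABOLIC,
        respiratory=category is AcidBaseCategory.MIXED or category in _SINGLE_RESPIRATORY,
    )


def classify_error(
    reference: AcidBaseCategory, predicted: AcidBaseCategory
) -> ErrorType:
    """Grade a (reference, predicted) pair on the severity taxonomy.

    Total over all 36 ordered pairs: 6 map to ``CORRECT``, exactly one
    (mixed read as normal) to ``FALSE_REASSURANCE``, four (mixed read as a
    single disorder) to ``MIXED_AS_SINGLE`` and the remaining 25 to
    ``OTHER_MISCLASSIFICATION``.
    """
    if predicted is reference:
        return ErrorType.CORRECT
    if reference is AcidBaseCategory.MIXED:
        if predicted is AcidBaseCategory.NORMAL:
            return ErrorType.FALSE_REASSURANCE
        if predicted in SINGLE_DISORDERS:
            return ErrorType.MIXED_AS_SINGLE
    return ErrorType.OTHER_MISCLASSIFICATION
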