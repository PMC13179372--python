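"""Cohort CSV I/O (long format) with schema validation.

One row per (case, evaluator): case_id, reference_category,
reference_metabolic, reference_respiratory, evaluator, predicted_category,
predicted_metabolic, predicted_respiratory. Categories use the six
canonical lower-snake tokens; booleans are 0/1. Reads collect every schema
violation (with line numbers) before failing, not just the first.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .categories import AcidBaseCategory, ComponentProfile
from .cohort import Assessment, CaseRecord, CohortDataset

COLUMNS = [
    "case_id",
    "reference_category",
    "reference_metabolic",
    "reference_respiratory",
    "evaluator",
    "predicted_category",
    "predicted_metabolic",
    "predicted_respiratory",
]

_VALID_TOKENS = {c.value for c in AcidBaseCategory}


class CohortSchemaError(ValueError):
    """Carries the full list of schema violations found in a cohort file."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "cohort file violates schema:\n  " + "\n  ".join(violations)
        )


def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    rows = []
    for case in dataset.cases:
        for evaluator in dataset.evaluators:
            a = case.assessment(evaluator)
            rows.append(
                {
                    "case_id": case.case_id,
                    "reference_category": case.reference_category.value,
                    "reference_metabolic": int(case.reference_components.metabolic),
                    "reference_respiratory": int(case.reference_components.respiratory),
                    "evaluator": evaluator,
                    "predicted_category": a.predicted_category.value,
                    "predicted_metabolic": int(a.predicted_components.metabolic),
                    "predicted_respiratory": int(a.predicted_components.respiratory),
                }
            )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_cohort(path: str | Path, provenance: str = "user") -> CohortDataset:
    """Parse and validate a long-format cohort CSV.

    Raises :class:`CohortSchemaError` enumerating every violation: missing
    columns, unknown category tokens or boolean codes (with line numbers),
    duplicate (case, evaluator) rows, incomplete evaluator coverage, and
    reference fields that disagree between rows of the same case.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    violations: list[str] = []

    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortSchemaError([f"missing columns: {missing_cols}"])

    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in ("reference_category", "predicted_category"):
            if row[col] not in _VALID_TOKENS:
                violations.append(
                    f"line {line}: unknown category token {row[col]!r} in {col}"
                )
        for col in (
            "reference_metabolic",
            "reference_respiratory",
            "predicted_metabolic",
            "predicted_respiratory",
        ):
            if row[col] not in {"0", "1"}:
                violations.append(
                    f"line {line}: boolean column {col} must be 0/1, got {row[col]!r}"
                )
        if not row["case_id"] or not row["evaluator"]:
            violations.append(f"line {line}: empty case_id or evaluator")

    if violations:
        raise CohortSchemaError(violations)

    dupes = df.duplicated(subset=["case_id", "evaluator"])
    for i in df.index[dupes]:
        violations.append(
            f"line {i + 2}: duplicate (case_id, evaluator) pair "
            f"({df.at[i, 'case_id']}, {df.at[i, 'evaluator']})"
        )

    evaluators = list(dict.fromkeys(df["evaluator"]))
    case_ids = list(dict.fromkeys(df["case_id"]))
    by_case = dict(tuple(df.groupby("case_id", sort=False)))
    for cid in case_ids:
        sub = by_case[cid]
        have = set(sub["evaluator"])
        missing = [e for e in evaluators if e not in have]
        if missing:
            violations.append(f"case {cid!r}: missing evaluator rows for {missing}")
        for col in ("reference_category", "reference_metabolic", "reference_respiratory"):
            if sub[col].nunique() > 1:
                violations.append(f"case {cid!r}: inconsistent {col} across rows")

    if violations:
        raise CohortSchemaError(violations)

    cases = []
    for cid in case_ids:
        sub = by_case[cid]
        first = sub.iloc[0]
        assessments = {
            r["evaluator"]: Assessment(
                predicted_category=AcidBaseCategory(r["predicted_category"]),
                predicted_components=ComponentProfile(
                    metabolic=r["predicted_metabolic"] == "1",
                    respiratory=r["predicted_respiratory"] == "1",
                ),
            )
            for _, r in sub.iterrows()
        }
        cases.append(
            CaseRecord(
                case_id=cid,
                reference_category=AcidBaseCategory(first["reference_category"]),
                reference_components=ComponentProfile(
                    metabolic=first["reference_metabolic"] == "1",
                    respiratory=first["reference_respiratory"] == "1",
                ),
                assessments=assessments,
            )
        )
    return CohortDataset(cases=cases, evaluators=evaluators, provenance=provenance)
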