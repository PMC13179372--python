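"""Parametric simulation of paired-evaluator cohorts.

The generator abstracts an evaluator as (i) a row-stochastic confusion
profile — for each reference category, a distribution over predicted
categories — and (ii) per-component detection probabilities (hit rate for
truly present components, false-flag rate for absent ones). Evaluators
are sampled independently given the reference category, and component
flags independently of the categorical call given the reference
components; simulation is at the label level only, with no blood-gas
physiology. Identical seed and configuration reproduce the cohort
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .categories import CATEGORY_ORDER, AcidBaseCategory, ComponentProfile
from .cohort import Assessment, CaseRecord, CohortDataset, derive_components

_TOL = 1e-9


def _as_row(dist: dict[AcidBaseCategory, float]) -> np.ndarray:
    return np.array([dist.get(cat, 0.0) for cat in CATEGORY_ORDER], dtype=float)


@dataclass(frozen=True)
class ComponentDetection:
    """Bernoulli rates for flagging each physiological component."""

    p_detect_metabolic: float
    p_detect_respiratory: float
    p_false_metabolic: float = 0.0
    p_false_respiratory: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "p_detect_metabolic",
            "p_detect_respiratory",
            "p_false_metabolic",
            "p_false_respiratory",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class EvaluatorProfile:
    """Row-conditional confusion distributions plus component detection."""

    confusion_rows: dict[AcidBaseCategory, dict[AcidBaseCategory, float]]
    component_detection: ComponentDetection

    def __post_init__(self) -> None:
        for ref in CATEGORY_ORDER:
            if ref not in self.confusion_rows:
                raise ValueError(f"missing confusion row for {ref.value}")
            row = _as_row(self.confusion_rows[ref])
            if np.any(row < 0) or np.any(row > 1):
                raise ValueError(f"probabilities out of [0,1] in row {ref.value}")
            if abs(row.sum() - 1.0) > _TOL:
                raise ValueError(
                    f"confusion row for {ref.value} sums to {row.sum()!r}, not 1"
                )

    def row(self, reference: AcidBaseCategory) -> np.ndarray:
        return _as_row(self.confusion_rows[reference])


def perfect_profile() -> EvaluatorProfile:
    """An evaluator that is always right, in category and components."""
    rows = {
        ref: {cat: 1.0 if cat is ref else 0.0 for cat in CATEGORY_ORDER}
        for ref in CATEGORY_ORDER
    }
    return EvaluatorProfile(rows, ComponentDetection(1.0, 1.0, 0.0, 0.0))


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    reference_distribution: dict[AcidBaseCategory, float]
    profiles: dict[str, EvaluatorProfile]
    seed: int
    provenance: str = "synthetic"
    case_id_prefix: str = "S"
    _ref_row: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if not self.profiles:
            raise ValueError("at least one evaluator profile is required")
        row = _as_row(self.reference_distribution)
        if np.any(row < 0) or abs(row.sum() - 1.0) > _TOL:
            raise ValueError("reference_distribution must be a probability vector")
        object.__setattr__(self, "_ref_row", row)


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Draw a cohort from the generative model; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    cats = np.array(CATEGORY_ORDER, dtype=object)
    ref_idx = rng.choice(6, size=config.n, p=config._ref_row)
    ref_cats = cats[ref_idx]

    pred_by_eval: dict[str, np.ndarray] = {}
    comp_by_eval: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for evaluator, profile in config.profiles.items():
        rows = np.stack([profile.row(ref) for ref in CATEGORY_ORDER])
        # inverse-CDF draw per case against its reference-conditional row
        cum = rows.cumsum(axis=1)[ref_idx]
        u = rng.random(config.n)
        pred_by_eval[evaluator] = cats[(u[:, None] < cum).argmax(axis=1)]

        det = profile.component_detection
        ref_met = np.array([derive_components(r).metabolic for r in ref_cats])
        ref_resp = np.array([derive_components(r).respiratory for r in ref_cats])
        p_met = np.where(ref_met, det.p_detect_metabolic, det.p_false_metabolic)
        p_resp = np.where(ref_resp, det.p_detect_respiratory, det.p_false_respiratory)
        comp_by_eval[evaluator] = (
            rng.random(config.n) < p_met,
            rng.random(config.n) < p_resp,
        )

    width = max(5, len(str(config.n)))
    cases = []
    for i in range(config.n):
        assessments = {}
        for evaluator in config.profiles:
            met, resp = comp_by_eval[evaluator]
            assessments[evaluator] = Assessment(
                predicted_category=pred_by_eval[evaluator][i],
                predicted_components=ComponentProfile(bool(met[i]), bool(resp[i])),
            )
        ref = ref_cats[i]
        cases.append(
            CaseRecord(
                case_id=f"{config.case_id_prefix}{i + 1:0{width}d}",
                reference_category=ref,
                reference_components=derive_components(ref),
                assessments=assessments,
            )
        )
    return CohortDataset(
        cases=cases,
        evaluators=list(config.profiles),
        provenance=config.provenance,
    )


def profile_from_fixture(dataset: CohortDataset, evaluator: str) -> EvaluatorProfile:
    """Empirical evaluator profile: reference-conditioned prediction
    frequencies and component detection/false-flag rates.

    Reference categories with no support get a uniform confusion row and a
    warning; component rates with empty denominators default to 0 with a
    warning.
    """
    dataset.require_evaluator(evaluator)
    rows: dict[AcidBaseCategory, dict[AcidBaseCategory, float]] = {}
    for ref in CATEGORY_ORDER:
        sub = [c for c in dataset.cases if c.reference_category is ref]
        if not sub:
            warnings.warn(
                f"no cases with reference {ref.value}; using a uniform row",
                stacklevel=2,
            )
            rows[ref] = {cat: 1 / 6 for cat in CATEGORY_ORDER}
            continue
        rows[ref] = {
            cat: sum(
                c.assessment(evaluator).predicted_category is cat for c in sub
            )
            / len(sub)
            for cat in CATEGORY_ORDER
        }

    def _rate(num: int, den: int, label: str) -> float:
        if den == 0:
            warnings.warn(f"no cases in {label} denominator; rate set to 0", stacklevel=3)
            return 0.0
        return num / den

    tallies = {key: [0, 0] for key in ("dm", "dr", "fm", "fr")}
    for case in dataset.cases:
        flags = case.assessment(evaluator).predicted_components
        for comp, detect_key, false_key in (
            ("metabolic", "dm", "fm"),
            ("respiratory", "dr", "fr"),
        ):
            present = getattr(case.reference_components, comp)
            flagged = getattr(flags, comp)
            key = detect_key if present else false_key
            tallies[key][0] += flagged
            tallies[key][1] += 1
    detection = ComponentDetection(
        p_detect_metabolic=_rate(*tallies["dm"], "metabolic-present"),
        p_detect_respiratory=_rate(*tallies["dr"], "respiratory-present"),
        p_false_metabolic=_rate(*tallies["fm"], "metabolic-absent"),
        p_false_respiratory=_rate(*tallies["fr"], "respiratory-absent"),
    )
    return EvaluatorProfile(rows, detection)
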