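"""Accuracy, agreement, stratified and component-level detection metrics.

All proportions come with exact Clopper-Pearson 95% intervals (the
binomial-tail inversion, computed through the beta-quantile identity);
Cohen's kappa carries the Fleiss-Cohen-Everitt large-sample standard
error. A percentile-bootstrap interval for accuracy is available as an
alternative to the exact one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .categories import CATEGORY_ORDER, AcidBaseCategory, ErrorType, classify_error
from .cohort import CohortDataset


@dataclass(frozen=True)
class DetectionMetrics:
    """A numerator/denominator proportion with exact 95% bounds."""

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    observed_agreement: float
    expected_agreement: float
    standard_error: float


class EmptyStratumError(ValueError):
    """A metric was requested on a stratum containing no cases."""


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial 95% (by default) interval for k successes in n trials.

    Lower bound is the p with upper-tail probability alpha/2 at k (0 when
    k = 0); upper bound the p with lower-tail probability alpha/2 (1 when
    k = n). Equivalently beta quantiles: B(alpha/2; k, n-k+1) and
    B(1-alpha/2; k+1, n-k).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def proportion_metrics(k: int, n: int, alpha: float = 0.05) -> DetectionMetrics:
    if n == 0:
        raise EmptyStratumError("denominator is zero; metric undefined")
    low, high = clopper_pearson(k, n, alpha)
    return DetectionMetrics(k, n, k / n, low, high)


def confusion_matrix(
    dataset: CohortDataset, evaluator: str
) -> tuple[np.ndarray, np.ndarray]:
    """6x6 counts (rows = predicted, columns = reference) in the fixed
    report order, plus row-wise proportions (zero rows stay zero)."""
    dataset.require_evaluator(evaluator)
    idx = {cat: i for i, cat in enumerate(CATEGORY_ORDER)}
    counts = np.zeros((6, 6), dtype=int)
    for case in dataset.cases:
        pred = case.assessment(evaluator).predicted_category
        counts[idx[pred], idx[case.reference_category]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    return counts, props


def correct_count(dataset: CohortDataset, evaluator: str) -> int:
    dataset.require_evaluator(evaluator)
    return sum(
        case.assessment(evaluator).predicted_category is case.reference_category
        for case in dataset.cases
    )


def overall_accuracy(
    dataset: CohortDataset,
    evaluator: str,
    *,
    method: str = "exact",
    n_boot: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> DetectionMetrics:
    """Proportion of cases matching the reference standard.

    ``method="exact"`` (default) gives Clopper-Pearson bounds;
    ``method="bootstrap"`` a seeded percentile-bootstrap interval.
    """
    k = correct_count(dataset, evaluator)
    n = dataset.n
    if method == "exact":
        return proportion_metrics(k, n, alpha)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        hits = np.array(
            [
                case.assessment(evaluator).predicted_category
                is case.reference_category
                for case in dataset.cases
            ],
            dtype=float,
        )
        draws = rng.integers(0, n, size=(n_boot, n))
        means = hits[draws].mean(axis=1)
        low, high = np.quantile(means, [alpha / 2, 1 - alpha / 2])
        return DetectionMetrics(k, n, k / n, float(low), float(high))
    raise ValueError(f"unknown CI method {method!r}")


def cohens_kappa(
    dataset: CohortDataset, evaluator: str, alpha: float = 0.05
) -> AgreementResult:
    """Unweighted Cohen's kappa of the evaluator against the reference.

    CI uses the Fleiss-Cohen-Everitt asymptotic variance with normal
    quantiles; raises on degenerate marginals (expected agreement 1).
    """
    dataset.require_evaluator(evaluator)
    n = dataset.n
    if n < 2:
        raise ValueError("kappa needs at least two cases")
    counts, _ = confusion_matrix(dataset, evaluator)
    p = counts / n
    row = p.sum(axis=1)  # predicted marginals
    col = p.sum(axis=0)  # reference marginals
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise ZeroDivisionError(
            "expected agreement is 1 (single-category marginals); kappa undefined"
        )
    kappa = (p_o - p_e) / (1 - p_e)

    # Fleiss, Cohen & Everitt asymptotic variance of kappa-hat
    diag = np.diag(p)
    term_a = float(np.sum(diag * (1 - (row + col) * (1 - kappa)) ** 2))
    # off-diagonal cell (i, j) pairs the reference marginal of the
    # predicted index with the predicted marginal of the reference index
    cross = (col[:, None] + row[None, :]) ** 2
    off = p * cross
    np.fill_diagonal(off, 0.0)
    term_b = (1 - kappa) ** 2 * float(off.sum())
    term_c = (kappa - p_e * (1 - kappa)) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - p_e) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(stats.norm.ppf(1 - alpha / 2))
    return AgreementResult(
        kappa=kappa,
        ci_low=kappa - z * se,
        ci_high=min(kappa + z * se, 1.0),
        observed_agreement=p_o,
        expected_agreement=p_e,
        standard_error=se,
    )


def _stratum_accuracy(
    dataset: CohortDataset, evaluator: str, mixed_stratum: bool
) -> DetectionMetrics:
    cases = [
        c
        for c in dataset.cases
        if (c.reference_category is AcidBaseCategory.MIXED) == mixed_stratum
    ]
    if not cases:
        name = "mixed" if mixed_stratum else "non-mixed"
        raise EmptyStratumError(f"{name} stratum is empty")
    k = sum(
        c.assessment(evaluator).predicted_category is c.reference_category
        for c in cases
    )
    return proportion_metrics(k, len(cases))


def complexity_stratified_accuracy(
    dataset: CohortDataset, evaluator: str
) -> tuple[DetectionMetrics, DetectionMetrics]:
    """Accuracy within the reference-mixed stratum and its complement.

    The two numerators always sum to the overall correct count.
    """
    dataset.require_evaluator(evaluator)
    return (
        _stratum_accuracy(dataset, evaluator, True),
        _stratum_accuracy(dataset, evaluator, False),
    )


def mixed_detection(
    dataset: CohortDataset, evaluator: str
) -> tuple[DetectionMetrics, DetectionMetrics]:
    """Sensitivity and specificity for calling the mixed category."""
    dataset.require_evaluator(evaluator)
    tp = fn = tn = fp = 0
    for case in dataset.cases:
        pred_mixed = (
            case.assessment(evaluator).predicted_category is AcidBaseCategory.MIXED
        )
        if case.reference_category is AcidBaseCategory.MIXED:
            tp += pred_mixed
            fn += not pred_mixed
        else:
            fp += pred_mixed
            tn += not pred_mixed
    if tp + fn == 0 or tn + fp == 0:
        raise EmptyStratumError("mixed detection needs both strata non-empty")
    return proportion_metrics(tp, tp + fn), proportion_metrics(tn, tn + fp)


def component_detection(
    dataset: CohortDataset, evaluator: str
) -> dict[str, tuple[DetectionMetrics, DetectionMetrics]]:
    """Multi-label sensitivity/specificity per physiological component.

    Returns ``{"metabolic": (sens, spec), "respiratory": (sens, spec)}``,
    each judged against the reference component flags independently of the
    categorical call.
    """
    dataset.require_evaluator(evaluator)
    out: dict[str, tuple[DetectionMetrics, DetectionMetrics]] = {}
    for comp in ("metabolic", "respiratory"):
        tp = fn = tn = fp = 0
        for case in dataset.cases:
            truth = getattr(case.reference_components, comp)
            flag = getattr(case.assessment(evaluator).predicted_components, comp)
            if truth:
                tp += flag
                fn += not flag
            else:
                fp += flag
                tn += not flag
        if tp + fn == 0 or tn + fp == 0:
            raise EmptyStratumError(
                f"{comp} component detection needs both strata non-empty"
            )
        out[comp] = (proportion_metrics(tp, tp + fn), proportion_metrics(tn, tn + fp))
    return out


@dataclass(frozen=True)
class FalseReassuranceResult:
    rate: DetectionMetrics
    p0: float
    p_value_two_sided: float
    p_value_greater: float


def false_reassurance(
    dataset: CohortDataset, evaluator: str, p0: float = 0.0
) -> FalseReassuranceResult:
    """Rate of mixed cases read as normal, with an exact binomial test.

    The null rate ``p0`` is an explicit parameter (0 gives a degenerate
    test that is significant at any alpha whenever a single false-normal
    occurs). Both the two-sided and the one-sided (greater) exact p-values
    are reported.
    """
    dataset.require_evaluator(evaluator)
    if not 0 <= p0 < 1:
        raise ValueError("p0 must lie in [0, 1)")
    mixed = [
        c for c in dataset.cases if c.reference_category is AcidBaseCategory.MIXED
    ]
    if not mixed:
        raise EmptyStratumError("no reference-mixed cases")
    k = sum(
        classify_error(
            c.reference_category, c.assessment(evaluator).predicted_category
        )
        is ErrorType.FALSE_REASSURANCE
        for c in mixed
    )
    n = len(mixed)
    return FalseReassuranceResult(
        rate=proportion_metrics(k, n),
        p0=p0,
        p_value_two_sided=float(stats.binomtest(k, n, p0).pvalue),
        p_value_greater=float(
            stats.binomtest(k, n, p0, alternative="greater").pvalue
        ),
    )
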