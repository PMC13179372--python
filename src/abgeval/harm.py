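"""Harm-weighted misclassification scoring and paired comparison.

Categorical accuracy treats every error alike; clinically they are not.
Each misclassification is scored by its severity tier — false reassurance
(mixed called normal) > mixed-as-single > everything else > correct (0) —
and evaluators are compared on mean per-case harm with a paired Wilcoxon
signed-rank test and a paired percentile bootstrap of the mean difference.

The study's numeric weights were never published; the shipped defaults are
the unique triple (anchored at 1.0 for false reassurance) that reproduces
both published mean harm scores given the canonical fixture's error-tier
counts. They are a modeling instrument, not estimates of true clinical
harm, and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import sqrt

import numpy as np
from scipy import stats

from .categories import AcidBaseCategory, ErrorType, classify_error
from .cohort import CohortDataset


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class HarmWeights:
    """Three-tier severity weights; correct classifications score 0.

    The hierarchy w_false_reassurance > w_mixed_as_single > w_other >= 0
    is enforced at construction.
    """

    w_false_reassurance: float
    w_mixed_as_single: float
    w_other: float

    def __post_init__(self) -> None:
        if not (
            self.w_false_reassurance > self.w_mixed_as_single > self.w_other >= 0
        ):
            raise ValueError(
                "harm weights must satisfy "
                "w_false_reassurance > w_mixed_as_single > w_other >= 0; got "
                f"({self.w_false_reassurance}, {self.w_mixed_as_single}, {self.w_other})"
            )

    def for_error(self, error: ErrorType) -> float:
        return {
            ErrorType.CORRECT: 0.0,
            ErrorType.FALSE_REASSURANCE: self.w_false_reassurance,
            ErrorType.MIXED_AS_SINGLE: self.w_mixed_as_single,
            ErrorType.OTHER_MISCLASSIFICATION: self.w_other,
        }[error]


# Calibrated against the canonical fixture's tier counts ({fr 0, ms 1,
# other 8} vs {fr 4, ms 5, other 5}) and the published means 0.064/0.184,
# with the false-reassurance anchor at 1.0: w_ms = 128/175, w_o = 54/175.
DEFAULT_WEIGHTS = HarmWeights(
    w_false_reassurance=1.0,
    w_mixed_as_single=float(Fraction(128, 175)),
    w_other=float(Fraction(54, 175)),
)


def harm_score(
    reference: AcidBaseCategory,
    predicted: AcidBaseCategory,
    weights: HarmWeights = DEFAULT_WEIGHTS,
) -> float:
    """Severity-tier weight of one (reference, predicted) pair."""
    return weights.for_error(classify_error(reference, predicted))


def per_case_scores(
    dataset: CohortDataset, evaluator: str, weights: HarmWeights = DEFAULT_WEIGHTS
) -> np.ndarray:
    dataset.require_evaluator(evaluator)
    return np.array(
        [
            harm_score(
                c.reference_category,
                c.assessment(evaluator).predicted_category,
                weights,
            )
            for c in dataset.cases
        ]
    )


def mean_harm(
    dataset: CohortDataset, evaluator: str, weights: HarmWeights = DEFAULT_WEIGHTS
) -> float:
    """Arithmetic mean per-case harm over all cases (correct cases count 0)."""
    return float(per_case_scores(dataset, evaluator, weights).mean())


def calibrate_weights(
    error_counts_a: dict[ErrorType, int],
    error_counts_b: dict[ErrorType, int],
    target_mean_a: float,
    target_mean_b: float,
    n: int,
    anchor: float = 1.0,
) -> HarmWeights:
    """Invert two published mean harm scores into a weight triple.

    With the false-reassurance weight anchored, the two mean-harm equations
    are linear in (w_mixed_as_single, w_other); solve the 2x2 system and
    enforce the severity hierarchy on the result.
    """

    def row(counts: dict[ErrorType, int]) -> tuple[float, float, float]:
        return (
            counts.get(ErrorType.MIXED_AS_SINGLE, 0),
            counts.get(ErrorType.OTHER_MISCLASSIFICATION, 0),
            counts.get(ErrorType.FALSE_REASSURANCE, 0) * anchor,
        )

    ms_a, o_a, fr_a = row(error_counts_a)
    ms_b, o_b, fr_b = row(error_counts_b)
    matrix = np.array([[ms_a, o_a], [ms_b, o_b]], dtype=float)
    rhs = np.array([n * target_mean_a - fr_a, n * target_mean_b - fr_b])
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise np.linalg.LinAlgError(
            "tier-count system is singular; weights are not identifiable"
        )
    w_ms, w_o = np.linalg.solve(matrix, rhs)
    return HarmWeights(anchor, float(w_ms), float(w_o))  # may raise on hierarchy


def count_error_tiers(dataset: CohortDataset, evaluator: str) -> dict[ErrorType, int]:
    dataset.require_evaluator(evaluator)
    counts = {e: 0 for e in ErrorType}
    for case in dataset.cases:
        err = classify_error(
            case.reference_category, case.assessment(evaluator).predicted_category
        )
        counts[err] += 1
    return counts


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

def _signed_ranks(diffs: np.ndarray, zero_method: str) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| for the nonzero differences under the given policy.

    ``wilcox`` discards zeros before ranking (classic); ``pratt`` ranks
    zeros with the rest, then drops them from the statistic.
    """
    d = np.asarray(diffs, dtype=float)
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            raise DegenerateTestError("all paired differences are zero")
        ranks = stats.rankdata(np.abs(d))
        return d, ranks
    if zero_method == "pratt":
        if not np.any(d != 0):
            raise DegenerateTestError("all paired differences are zero")
        ranks = stats.rankdata(np.abs(d))
        keep = d != 0
        return d[keep], ranks[keep]
    raise ValueError(f"unknown zero_method {zero_method!r}")


def _exact_signed_rank_p(d: np.ndarray, ranks: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over the rank-sum lattice.

    Midranks are doubled to integers; each |d_i| independently lands its
    rank in W+ with probability 1/2 under the null, so the null pmf of
    2*W+ is a polynomial product evaluated by convolution. Two-sided p is
    the doubled smaller tail, capped at 1.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w_plus = float(np.rint(2 * ranks[d > 0].sum()))
    cdf = np.cumsum(pmf)
    p_le = float(cdf[int(w_plus)])
    p_ge = float(pmf[int(w_plus):].sum())
    return min(1.0, 2 * min(p_le, p_ge))


def _approx_signed_rank_p(d: np.ndarray, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction on the rank variance."""
    w_plus = ranks[d > 0].sum()
    mean = ranks.sum() / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = ranks.size * (ranks.size + 1) * (2 * ranks.size + 1) / 24 - (
        (tie_counts**3 - tie_counts).sum() / 48
    )
    # under heavy ties var can shrink; guard the degenerate case
    if var <= 0:
        raise DegenerateTestError("rank variance is zero under ties")
    z = (w_plus - mean) / sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    diffs: np.ndarray,
    *,
    zero_method: str = "wilcox",
    exact_threshold: int = 25,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Exact (tie-aware, via the rank-sum convolution) when the number of
    nonzero differences is at most ``exact_threshold``; otherwise the
    normal approximation with tie correction.
    """
    d, ranks = _signed_ranks(np.asarray(diffs, dtype=float), zero_method)
    if d.size <= exact_threshold:
        return _exact_signed_rank_p(d, ranks)
    return _approx_signed_rank_p(d, ranks)


def paired_harm_test(
    dataset: CohortDataset,
    evaluator_a: str,
    evaluator_b: str,
    weights: HarmWeights = DEFAULT_WEIGHTS,
    *,
    zero_method: str = "wilcox",
) -> float:
    """Wilcoxon signed-rank p-value on per-case harm differences (B - A)."""
    scores_a = per_case_scores(dataset, evaluator_a, weights)
    scores_b = per_case_scores(dataset, evaluator_b, weights)
    return wilcoxon_signed_rank(scores_b - scores_a, zero_method=zero_method)


@dataclass(frozen=True)
class HarmSummary:
    """Paired harm comparison: means, difference, test and bootstrap CI."""

    evaluator_a: str
    evaluator_b: str
    mean_harm_a: float
    mean_harm_b: float
    mean_difference: float  # B minus A
    wilcoxon_p: float | None  # None when every paired difference is zero
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    per_case_scores_a: np.ndarray
    per_case_scores_b: np.ndarray


def bootstrap_mean_difference(
    dataset: CohortDataset,
    evaluator_a: str,
    evaluator_b: str,
    weights: HarmWeights = DEFAULT_WEIGHTS,
    n_bootstrap: int = 5000,
    seed: int = 0,
    *,
    zero_method: str = "wilcox",
) -> HarmSummary:
    """Paired case-level percentile bootstrap of the mean harm difference.

    Cases are resampled with replacement as units, both evaluators' scores
    travelling together — the only resampling consistent with the paired
    design. Deterministic for a fixed seed.
    """
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap iteration")
    scores_a = per_case_scores(dataset, evaluator_a, weights)
    scores_b = per_case_scores(dataset, evaluator_b, weights)
    diffs = scores_b - scores_a
    n = diffs.size
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(n_bootstrap, n))
    boot_means = diffs[draws].mean(axis=1)
    low, high = np.quantile(boot_means, [0.025, 0.975])
    try:
        wilcoxon_p: float | None = wilcoxon_signed_rank(diffs, zero_method=zero_method)
    except DegenerateTestError:
        wilcoxon_p = None  # evaluators agree case-for-case; no test to run
    return HarmSummary(
        evaluator_a=evaluator_a,
        evaluator_b=evaluator_b,
        mean_harm_a=float(scores_a.mean()),
        mean_harm_b=float(scores_b.mean()),
        mean_difference=float(diffs.mean()),
        wilcoxon_p=wilcoxon_p,
        ci_low=float(low),
        ci_high=float(high),
        n_bootstrap=n_bootstrap,
        seed=seed,
        per_case_scores_a=scores_a,
        per_case_scores_b=scores_b,
    )
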