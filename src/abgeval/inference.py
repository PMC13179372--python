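"""Paired categorical comparison and post-hoc power.

Two evaluators reading the same cases form a paired 2x2 correctness table;
discordant pairs carry all the information about a difference in overall
accuracy (exact McNemar). Achieved power for the observed accuracy gap is
approximated through Cohen's arcsine effect size h for two proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, sqrt

from scipy import stats

from .cohort import CohortDataset


@dataclass(frozen=True)
class PairedCorrectnessTable:
    """Counts of case-level correctness agreement between two evaluators."""

    both_correct: int
    a_only_correct: int
    b_only_correct: int
    both_wrong: int

    def __post_init__(self) -> None:
        if min(
            self.both_correct, self.a_only_correct, self.b_only_correct, self.both_wrong
        ) < 0:
            raise ValueError("all cell counts must be non-negative")

    @property
    def n(self) -> int:
        return (
            self.both_correct
            + self.a_only_correct
            + self.b_only_correct
            + self.both_wrong
        )


def paired_correctness_table(
    dataset: CohortDataset, evaluator_a: str, evaluator_b: str
) -> PairedCorrectnessTable:
    """Cross-tabulate case-level correctness of two evaluators.

    Marginals reproduce each evaluator's correct count: a + b for the
    first, a + c for the second.
    """
    dataset.require_evaluator(evaluator_a)
    dataset.require_evaluator(evaluator_b)
    a = b = c = d = 0
    for case in dataset.cases:
        hit_a = (
            case.assessment(evaluator_a).predicted_category
            is case.reference_category
        )
        hit_b = (
            case.assessment(evaluator_b).predicted_category
            is case.reference_category
        )
        if hit_a and hit_b:
            a += 1
        elif hit_a:
            b += 1
        elif hit_b:
            c += 1
        else:
            d += 1
    return PairedCorrectnessTable(a, b, c, d)


def mcnemar_exact(table: PairedCorrectnessTable) -> float:
    """Exact two-sided McNemar p-value on the discordant pairs.

    Under the null the smaller discordant count is Binomial(b + c, 1/2);
    the two-sided p doubles the smaller tail and caps at 1. No discordance
    gives p = 1.
    """
    b, c = table.a_only_correct, table.b_only_correct
    m = b + c
    if m == 0:
        return 1.0
    k = min(b, c)
    return min(1.0, 2 * float(stats.binom.cdf(k, m, 0.5)))


def mcnemar_chi2(table: PairedCorrectnessTable, correction: bool = True) -> float:
    """Chi-square McNemar variant (optionally continuity-corrected)."""
    b, c = table.a_only_correct, table.b_only_correct
    if b + c == 0:
        return 1.0
    num = (abs(b - c) - 1) ** 2 if correction else (b - c) ** 2
    return float(stats.chi2.sf(num / (b + c), df=1))


def mcnemar_midp(table: PairedCorrectnessTable) -> float:
    """Mid-p McNemar variant: exact two-sided minus the point probability."""
    b, c = table.a_only_correct, table.b_only_correct
    m = b + c
    if m == 0:
        return 1.0
    k = min(b, c)
    exact = 2 * float(stats.binom.cdf(k, m, 0.5))
    return min(1.0, exact - float(stats.binom.pmf(k, m, 0.5)))


def cohens_h(p1: float, p2: float) -> float:
    """Arcsine effect size for two proportions: 2 asin sqrt(p1) - 2 asin sqrt(p2)."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    return 2 * asin(sqrt(p1)) - 2 * asin(sqrt(p2))


@dataclass(frozen=True)
class PowerResult:
    h: float
    n_per_group: int
    alpha: float
    power: float


def posthoc_power_two_proportions(
    h: float, n_per_group: int, alpha: float = 0.05
) -> PowerResult:
    """Achieved power of the two-proportion z-test at effect size ``h``.

    One-tail approximation of the two-sided test:
    power = Phi(|h| * sqrt(n/2) - z_{1-alpha/2}). This is the standard
    unpaired arcsine approximation; applied to a paired design it is a
    deliberate (conservative, convention-following) simplification.
    """
    if n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = float(stats.norm.ppf(1 - alpha / 2))
    power = float(stats.norm.cdf(abs(h) * sqrt(n_per_group / 2) - z_crit))
    return PowerResult(h=h, n_per_group=n_per_group, alpha=alpha, power=power)
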