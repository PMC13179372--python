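"""Accuracy, agreement and detection metrics against independent oracles."""

import math

import numpy as np
import pytest

from abgeval import (
    CHATGPT,
    PHYSICIAN,
    AcidBaseCategory,
    CohortDataset,
    clopper_pearson,
    cohens_kappa,
    complexity_stratified_accuracy,
    component_detection,
    false_reassurance,
    make_case,
    mixed_detection,
    overall_accuracy,
)
from abgeval.metrics import EmptyStratumError

C = AcidBaseCategory
ALPHA = 0.05


# ---------------------------------------------------------------------------
# Clopper-Pearson oracle: direct tail inversion by bisection on exact
# binomial sums (integer combinatorics only; independent of the beta
# quantile route used by the implementation).

def _upper_tail(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def _lower_tail(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def _bisect(f, target, lo=0.0, hi=1.0, increasing=True):
    for _ in range(80):
        mid = (lo + hi) / 2
        if (f(mid) < target) == increasing:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _oracle_cp(k, n):
    low = 0.0 if k == 0 else _bisect(lambda p: _upper_tail(k, n, p), ALPHA / 2)
    high = (
        1.0
        if k == n
        else _bisect(lambda p: _lower_tail(k, n, p), ALPHA / 2, increasing=False)
    )
    return low, high


@pytest.mark.parametrize("n", range(1, 31))
def test_clopper_pearson_matches_tail_inversion(n):
    for k in range(n + 1):
        low, high = clopper_pearson(k, n)
        o_low, o_high = _oracle_cp(k, n)
        assert low == pytest.approx(o_low, abs=1e-9)
        assert high == pytest.approx(o_high, abs=1e-9)
        assert low <= k / n <= high


# ---------------------------------------------------------------------------
# fixture-level values

def test_overall_accuracy(fixture_cohort):
    phys = overall_accuracy(fixture_cohort, PHYSICIAN)
    gpt = overall_accuracy(fixture_cohort, CHATGPT)
    assert (phys.numerator, phys.denominator, phys.estimate) == (41, 50, 0.82)
    assert (gpt.numerator, gpt.denominator, gpt.estimate) == (36, 50, 0.72)


def test_overall_accuracy_bootstrap_ci_is_seeded(fixture_cohort):
    a = overall_accuracy(fixture_cohort, CHATGPT, method="bootstrap", seed=7)
    b = overall_accuracy(fixture_cohort, CHATGPT, method="bootstrap", seed=7)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    assert a.ci_low < 0.72 < a.ci_high


def test_kappa_rounds_to_published_values(fixture_cohort):
    phys = cohens_kappa(fixture_cohort, PHYSICIAN)
    gpt = cohens_kappa(fixture_cohort, CHATGPT)
    assert round(phys.kappa, 2) == 0.73
    assert round(gpt.kappa, 2) == 0.63
    for res in (phys, gpt):
        assert res.ci_low < res.kappa < res.ci_high <= 1.0
        pe = res.expected_agreement
        assert res.kappa == pytest.approx(
            (res.observed_agreement - pe) / (1 - pe)
        )


def _kappa_case_by_case(dataset, evaluator):
    """Second path: kappa from raw label pairs, no confusion matrix."""
    refs = [c.reference_category for c in dataset.cases]
    preds = [c.assessment(evaluator).predicted_category for c in dataset.cases]
    n = len(refs)
    p_o = sum(r is p for r, p in zip(refs, preds)) / n
    p_e = sum(
        (preds.count(cat) / n) * (refs.count(cat) / n) for cat in AcidBaseCategory
    )
    return (p_o - p_e) / (1 - p_e)


@pytest.mark.parametrize("evaluator", [PHYSICIAN, CHATGPT])
def test_kappa_two_path_equivalence(fixture_cohort, evaluator):
    matrix_path = cohens_kappa(fixture_cohort, evaluator).kappa
    assert matrix_path == pytest.approx(
        _kappa_case_by_case(fixture_cohort, evaluator), abs=1e-12
    )


@pytest.mark.parametrize("evaluator", [PHYSICIAN, CHATGPT])
def test_kappa_cross_checked_against_reference_libraries(fixture_cohort, evaluator):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    inter_rater = pytest.importorskip("statsmodels.stats.inter_rater")
    refs = [c.reference_category.value for c in fixture_cohort.cases]
    preds = [
        c.assessment(evaluator).predicted_category.value
        for c in fixture_cohort.cases
    ]
    ours = cohens_kappa(fixture_cohort, evaluator)
    assert ours.kappa == pytest.approx(
        sklearn_metrics.cohen_kappa_score(refs, preds), abs=1e-12
    )
    from abgeval import confusion_matrix

    counts, _ = confusion_matrix(fixture_cohort, evaluator)
    sm = inter_rater.cohens_kappa(counts, return_results=True)
    assert ours.kappa == pytest.approx(sm.kappa, abs=1e-12)
    assert ours.standard_error == pytest.approx(np.sqrt(sm.var_kappa), rel=1e-6)


def test_kappa_degenerate_marginals_raise():
    cases = [
        make_case(f"X{i}", C.MIXED, {"e": C.MIXED}) for i in range(3)
    ]
    ds = CohortDataset(cases, ["e"])
    with pytest.raises(ZeroDivisionError):
        cohens_kappa(ds, "e")


def test_kappa_independence_gives_zero():
    """2-category layout with every cell the product of its marginals."""
    cases = []
    i = 0
    for ref, pred, count in [
        (C.NORMAL, C.NORMAL, 4),
        (C.NORMAL, C.MIXED, 4),
        (C.MIXED, C.NORMAL, 1),
        (C.MIXED, C.MIXED, 1),
    ]:
        for _ in range(count):
            cases.append(make_case(f"K{i}", ref, {"e": pred}))
            i += 1
    assert cohens_kappa(CohortDataset(cases, ["e"]), "e").kappa == pytest.approx(0.0)


def test_stratified_accuracy(fixture_cohort):
    phys_mixed, phys_single = complexity_stratified_accuracy(fixture_cohort, PHYSICIAN)
    assert (phys_mixed.numerator, phys_mixed.denominator) == (23, 24)
    assert (phys_single.numerator, phys_single.denominator) == (18, 26)
    gpt_mixed, gpt_single = complexity_stratified_accuracy(fixture_cohort, CHATGPT)
    assert (gpt_mixed.numerator, gpt_mixed.denominator) == (15, 24)
    # stratum numerators always recompose the overall correct count
    assert phys_mixed.numerator + phys_single.numerator == 41
    assert gpt_mixed.numerator + gpt_single.numerator == 36


def test_mixed_detection(fixture_cohort):
    sens_p, spec_p = mixed_detection(fixture_cohort, PHYSICIAN)
    sens_g, spec_g = mixed_detection(fixture_cohort, CHATGPT)
    assert (sens_p.numerator, sens_p.denominator) == (23, 24)
    assert (spec_p.numerator, spec_p.denominator) == (19, 26)
    assert (sens_g.numerator, sens_g.denominator) == (15, 24)
    assert (spec_g.numerator, spec_g.denominator) == (23, 26)


def test_component_detection(fixture_cohort):
    phys = component_detection(fixture_cohort, PHYSICIAN)
    gpt = component_detection(fixture_cohort, CHATGPT)
    assert (phys["metabolic"][0].numerator, phys["metabolic"][0].denominator) == (34, 35)
    assert (phys["respiratory"][0].numerator, phys["respiratory"][0].denominator) == (34, 34)
    assert phys["respiratory"][0].estimate == 1.0
    assert (gpt["metabolic"][0].numerator, gpt["metabolic"][0].denominator) == (31, 35)
    assert (gpt["respiratory"][0].numerator, gpt["respiratory"][0].denominator) == (30, 34)


def test_false_reassurance_rates_and_exact_test(fixture_cohort):
    gpt = false_reassurance(fixture_cohort, CHATGPT, p0=0.05)
    assert (gpt.rate.numerator, gpt.rate.denominator) == (4, 24)
    assert gpt.rate.estimate == pytest.approx(1 / 6)
    # one-sided exact tail against p0 = 0.05, oracle by direct summation
    oracle = 1 - sum(
        math.comb(24, i) * 0.05**i * 0.95 ** (24 - i) for i in range(4)
    )
    assert gpt.p_value_greater == pytest.approx(oracle, abs=1e-12)

    phys = false_reassurance(fixture_cohort, PHYSICIAN)
    assert (phys.rate.numerator, phys.rate.denominator) == (0, 24)
    # closed-form exact upper bound for zero successes
    assert phys.rate.ci_high == pytest.approx(1 - 0.025 ** (1 / 24), abs=1e-9)
    assert phys.rate.ci_low == 0.0


def test_false_reassurance_rejects_bad_null(fixture_cohort):
    with pytest.raises(ValueError):
        false_reassurance(fixture_cohort, CHATGPT, p0=1.0)


def test_empty_stratum_flagged():
    ds = CohortDataset(
        [make_case("A1", C.NORMAL, {"e": C.NORMAL})], ["e"]
    )
    with pytest.raises(EmptyStratumError):
        complexity_stratified_accuracy(ds, "e")
    with pytest.raises(EmptyStratumError):
        false_reassurance(ds, "e")


def test_unknown_evaluator_rejected(fixture_cohort):
    with pytest.raises(KeyError, match="nobody"):
        overall_accuracy(fixture_cohort, "nobody")
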