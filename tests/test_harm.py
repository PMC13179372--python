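"""Harm-weighted scoring, weight calibration, Wilcoxon and bootstrap."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from abgeval import (
    CHATGPT,
    DEFAULT_WEIGHTS,
    PHYSICIAN,
    AcidBaseCategory,
    CohortDataset,
    ErrorType,
    HarmWeights,
    bootstrap_mean_difference,
    calibrate_weights,
    count_error_tiers,
    harm_score,
    make_case,
    mean_harm,
    paired_harm_test,
    wilcoxon_signed_rank,
)
from abgeval.harm import DegenerateTestError

C = AcidBaseCategory


def test_weight_hierarchy_enforced():
    HarmWeights(1.0, 0.5, 0.1)
    for bad in [(0.5, 1.0, 0.1), (1.0, 0.1, 0.5), (1.0, 1.0, 0.5), (1.0, 0.5, -0.1)]:
        with pytest.raises(ValueError):
            HarmWeights(*bad)


def test_harm_score_tier_lookup():
    assert harm_score(C.MIXED, C.NORMAL) == DEFAULT_WEIGHTS.w_false_reassurance == 1.0
    assert harm_score(C.MIXED, C.RESPIRATORY_ACIDOSIS) == DEFAULT_WEIGHTS.w_mixed_as_single
    assert harm_score(C.METABOLIC_ACIDOSIS, C.MIXED) == DEFAULT_WEIGHTS.w_other
    for cat in C:
        assert harm_score(cat, cat) == 0.0


def test_fixture_error_tiers(fixture_cohort):
    phys = count_error_tiers(fixture_cohort, PHYSICIAN)
    gpt = count_error_tiers(fixture_cohort, CHATGPT)
    assert phys == {
        ErrorType.CORRECT: 41,
        ErrorType.FALSE_REASSURANCE: 0,
        ErrorType.MIXED_AS_SINGLE: 1,
        ErrorType.OTHER_MISCLASSIFICATION: 8,
    }
    assert gpt == {
        ErrorType.CORRECT: 36,
        ErrorType.FALSE_REASSURANCE: 4,
        ErrorType.MIXED_AS_SINGLE: 5,
        ErrorType.OTHER_MISCLASSIFICATION: 5,
    }


def test_fixture_mean_harm(fixture_cohort):
    assert mean_harm(fixture_cohort, PHYSICIAN) == pytest.approx(0.064, abs=1e-12)
    assert mean_harm(fixture_cohort, CHATGPT) == pytest.approx(0.184, abs=1e-12)


def test_calibration_recovers_default_weights(fixture_cohort):
    """Inverting the two published means on the fixture's tier counts
    yields exactly the shipped default triple: (1, 128/175, 54/175)."""
    weights = calibrate_weights(
        count_error_tiers(fixture_cohort, PHYSICIAN),
        count_error_tiers(fixture_cohort, CHATGPT),
        target_mean_a=0.064,
        target_mean_b=0.184,
        n=50,
    )
    assert weights.w_false_reassurance == 1.0
    assert weights.w_mixed_as_single == pytest.approx(0.731428571428, abs=1e-9)
    assert weights.w_other == pytest.approx(0.308571428571, abs=1e-9)
    # and the recovered weights reproduce both targets exactly
    assert mean_harm(fixture_cohort, PHYSICIAN, weights) == pytest.approx(0.064)
    assert mean_harm(fixture_cohort, CHATGPT, weights) == pytest.approx(0.184)


def test_calibration_singular_system_raises():
    counts = {ErrorType.MIXED_AS_SINGLE: 2, ErrorType.OTHER_MISCLASSIFICATION: 2}
    with pytest.raises(np.linalg.LinAlgError):
        calibrate_weights(counts, counts, 0.1, 0.1, n=50)


def test_calibration_hierarchy_violation_raises():
    a = {ErrorType.MIXED_AS_SINGLE: 1, ErrorType.OTHER_MISCLASSIFICATION: 0}
    b = {ErrorType.MIXED_AS_SINGLE: 0, ErrorType.OTHER_MISCLASSIFICATION: 1}
    # forces w_other > w_mixed_as_single
    with pytest.raises(ValueError):
        calibrate_weights(a, b, 0.001, 0.01, n=50)


@given(
    scale=st.floats(min_value=0.05, max_value=10),
    w_ms=st.floats(min_value=0.4, max_value=0.9),
    w_o=st.floats(min_value=0.05, max_value=0.35),
)
def test_mean_harm_is_linear_in_weights(scale, w_ms, w_o):
    fixture = _FIXTURE
    base = HarmWeights(1.0, w_ms, w_o)
    scaled = HarmWeights(scale * 1.0, scale * w_ms, scale * w_o)
    for ev in (PHYSICIAN, CHATGPT):
        assert mean_harm(fixture, ev, scaled) == pytest.approx(
            scale * mean_harm(fixture, ev, base), rel=1e-9
        )


# hypothesis redraws per example; build the fixture once at module scope
from abgeval import build_canonical_fixture  # noqa: E402

_FIXTURE = build_canonical_fixture()


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank: exact path vs brute-force sign enumeration

def _oracle_wilcoxon(diffs):
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        np.sum(ranks[list(signs)])
        for signs in itertools.product([False, True], repeat=d.size)
    ]
    ws = np.array([w for w in ws])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.mark.parametrize("seed", range(8))
def test_exact_wilcoxon_equals_enumeration(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 12))
    # heavy-tie regime: values on a coarse grid, like tiered harm scores
    diffs = rng.choice([-1.0, -0.5, 0.0, 0.3, 0.5, 1.0], size=m)
    if not np.any(diffs != 0):
        diffs[0] = 1.0
    assert wilcoxon_signed_rank(diffs) == pytest.approx(
        _oracle_wilcoxon(diffs), abs=1e-12
    )


def test_exact_wilcoxon_all_positive_five():
    # 2 of 32 sign assignments are as extreme: the all-plus and all-minus
    assert wilcoxon_signed_rank([1.0, 1.0, 1.0, 1.0, 1.0]) == pytest.approx(2 / 32)


def test_exact_wilcoxon_antisymmetric_pair_is_central():
    assert wilcoxon_signed_rank([0.5, -0.5]) == pytest.approx(1.0)


def test_wilcoxon_matches_scipy_exact_when_tie_free():
    rng = np.random.default_rng(42)
    diffs = rng.normal(0.3, 1.0, size=15)
    expected = stats.wilcoxon(diffs, method="exact").pvalue
    assert wilcoxon_signed_rank(diffs) == pytest.approx(expected, abs=1e-12)


def test_wilcoxon_approx_path_matches_scipy():
    rng = np.random.default_rng(3)
    diffs = rng.normal(0.2, 1.0, size=60)
    expected = stats.wilcoxon(
        diffs, method="approx", correction=False
    ).pvalue
    assert wilcoxon_signed_rank(diffs) == pytest.approx(expected, rel=1e-9)


def test_wilcoxon_all_zero_raises():
    with pytest.raises(DegenerateTestError):
        wilcoxon_signed_rank([0.0, 0.0, 0.0])


def test_zero_policy_pratt_differs_but_both_exact():
    diffs = [0.0, 0.0, 1.0, 1.0, -0.5]
    p_wilcox = wilcoxon_signed_rank(diffs, zero_method="wilcox")
    p_pratt = wilcoxon_signed_rank(diffs, zero_method="pratt")
    assert 0 < p_wilcox <= 1 and 0 < p_pratt <= 1


def test_paired_harm_test_on_fixture_is_significant(fixture_cohort):
    p = paired_harm_test(fixture_cohort, PHYSICIAN, CHATGPT)
    assert p < 0.05
    # regression pin for the package's own exact path (13 nonzero diffs)
    assert p == pytest.approx(0.014404296875, abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_constant_differences_collapse():
    cases = [
        make_case(f"B{i}", C.MIXED, {"a": C.MIXED, "b": C.NORMAL}) for i in range(6)
    ]
    ds = CohortDataset(cases, ["a", "b"])
    res = bootstrap_mean_difference(ds, "a", "b", n_bootstrap=200, seed=5)
    assert res.ci_low == res.ci_high == res.mean_difference == 1.0


def test_bootstrap_fixture_summary(fixture_cohort):
    res = bootstrap_mean_difference(
        fixture_cohort, PHYSICIAN, CHATGPT, n_bootstrap=5000, seed=1
    )
    assert res.mean_harm_a == pytest.approx(0.064)
    assert res.mean_harm_b == pytest.approx(0.184)
    assert res.mean_difference == pytest.approx(0.12)
    assert res.ci_low > 0  # interval excludes zero
    assert res.ci_low < 0.12 < res.ci_high
    again = bootstrap_mean_difference(
        fixture_cohort, PHYSICIAN, CHATGPT, n_bootstrap=5000, seed=1
    )
    assert (res.ci_low, res.ci_high) == (again.ci_low, again.ci_high)


def test_bootstrap_ci_narrows_with_cohort_size():
    """On constant-profile synthetic cohorts the percentile interval
    centers on the true mean difference and tightens as n grows."""
    from abgeval import ComponentDetection, EvaluatorProfile, GeneratorConfig, generate_cohort

    rows_correct = {
        ref: {cat: 1.0 if cat is ref else 0.0 for cat in C} for ref in C
    }
    rows_wrongish = {
        ref: {
            cat: (0.7 if cat is ref else (0.3 if cat is C.NORMAL else 0.0))
            for cat in C
        }
        for ref in C
    }
    rows_wrongish[C.NORMAL] = {cat: 1.0 if cat is C.NORMAL else 0.0 for cat in C}
    det = ComponentDetection(1.0, 1.0)
    widths = []
    for n in (100, 1600):
        cfg = GeneratorConfig(
            n=n,
            reference_distribution={
                cat: (0.5 if cat is C.MIXED else 0.1) for cat in C
            },
            profiles={
                "good": EvaluatorProfile(rows_correct, det),
                "bad": EvaluatorProfile(rows_wrongish, det),
            },
            seed=11,
        )
        ds = generate_cohort(cfg)
        res = bootstrap_mean_difference(ds, "good", "bad", n_bootstrap=400, seed=2)
        widths.append(res.ci_high - res.ci_low)
        assert res.ci_low < res.mean_difference < res.ci_high
    assert widths[1] < widths[0] / 2
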