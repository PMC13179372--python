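"""Complexity-stratified and multi-label component detection.

Categorical accuracy hides *where* an evaluator fails. Stratifying by
reference complexity (mixed vs single disorders) and decomposing each
diagnosis into metabolic/respiratory components exposes the asymmetry.
"""

from abgeval import (
    build_canonical_fixture,
    complexity_stratified_accuracy,
    component_detection,
    false_reassurance,
    mixed_detection,
)

cohort = build_canonical_fixture()

for evaluator in cohort.evaluators:
    mixed_acc, single_acc = complexity_stratified_accuracy(cohort, evaluator)
    sens, spec = mixed_detection(cohort, evaluator)
    comps = component_detection(cohort, evaluator)
    fr = false_reassurance(cohort, evaluator, p0=0.05)
    print(f"\n{evaluator}")
    print(
        f"  accuracy on mixed cases   {mixed_acc.numerator}/{mixed_acc.denominator}"
        f" = {mixed_acc.estimate:.2f}; on single/normal "
        f"{single_acc.numerator}/{single_acc.denominator} = {single_acc.estimate:.2f}"
    )
    print(
        f"  mixed sens {sens.numerator}/{sens.denominator} ({sens.estimate:.2f}), "
        f"spec {spec.numerator}/{spec.denominator} ({spec.estimate:.2f})"
    )
    for comp, (c_sens, c_spec) in comps.items():
        print(
            f"  {comp:<11} component: sens {c_sens.numerator}/{c_sens.denominator} "
            f"({c_sens.estimate:.2f}), spec {c_spec.numerator}/{c_spec.denominator} "
            f"({c_spec.estimate:.2f})"
        )
    print(
        f"  false reassurance {fr.rate.numerator}/{fr.rate.denominator} "
        f"({fr.rate.estimate:.1%}; exact 95% CI {fr.rate.ci_low:.3f}-{fr.rate.ci_high:.3f}); "
        f"exact one-sided p vs null rate 5%: {fr.p_value_greater:.4f}"
    )
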