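# Methods

## Setting and data model

Fifty adult ICU cases were each interpreted three ways: by the attending
ICU physician, by an AI chat assistant given a standardized structured
vignette, and by a blinded expert panel whose call is the reference
standard. `abgeval` models this as a `CohortDataset`: an ordered list of
cases, each carrying a reference category, reference component flags, and
one assessment (predicted category + predicted component flags) per
evaluator on the roster. Everything generalizes to ≥ 1 evaluators; paired
statistics run over every evaluator pair.

Free-text interpretations are collapsed onto six exclusive categories
(normal, metabolic acidosis, metabolic alkalosis, respiratory acidosis,
respiratory alkalosis, mixed) by an ordered keyword rule table
(`data/harmonization_rules.json`): first match wins, keywords match at
word starts case-insensitively, compensation rules precede dual-disorder
rules so that "metabolic acidosis with respiratory compensation" stays a
single disorder while two primary disorders named independently map to
mixed. The table is deliberately dumb — deterministic and auditable —
and fully replaceable. Whether the original coders credited a component
mentioned only as "compensation" is unknowable from the published
material; for that reason predicted component flags are an independent
input channel and are only *derived* from the predicted category when the
input supplies none.

## Error taxonomy and harm model

Misclassifications are graded on three tiers: **false reassurance**
(reference mixed, predicted normal), **mixed-as-single** (reference
mixed, predicted one primary disorder), and **other** (every remaining
disagreement). Overclassification — a single/normal case called mixed —
is placed in the residual tier: the published hierarchy names only the
two mixed-specific tiers above a residual, and over-triage is the
clinically benign direction here. Over the 36 ordered category pairs the
taxonomy partitions as 6 correct / 1 / 4 / 25 (enumerated in tests).

Per-case harm is the tier weight (correct = 0); an evaluator's summary is
the arithmetic mean over all cases. The study's numeric weights were
never published, so the defaults are *calibrated*: with the
false-reassurance weight anchored at 1.0, the two published means (0.064
and 0.184) and the canonical cohort's tier counts ({0, 1, 8} and
{4, 5, 5} over n = 50) form a nonsingular 2×2 linear system whose unique
solution is w_MS = 128/175 ≈ 0.7314 and w_other = 54/175 ≈ 0.3086 —
which happens to respect the hierarchy, a nontrivial consistency check on
the published numbers. `calibrate_weights` performs this inversion for
any inputs and rejects hierarchy-violating solutions. Mean harm is linear
in the weights, so only weight *ratios* matter to the paired tests.

Evaluators are compared on per-case harm differences with the Wilcoxon
signed-rank test. Zeros are discarded before ranking (classic Wilcoxon;
the zero-inclusive Pratt variant is available via `zero_method="pratt"` —
the published analysis does not say which was used, and with 37 of 50
zero differences the choice is consequential). With ≤ 25 nonzero
differences the null distribution is computed exactly by dynamic
programming over the doubled midranks (ties are therefore handled
exactly; the two-sided p doubles the smaller tail, capped at 1); beyond
that, the normal approximation with the standard tie correction is used.
The 95% CI for the mean difference is a percentile bootstrap (default
5,000 iterations, seeded) resampling *cases* with replacement so both
evaluators' scores travel together — the only resampling unit that
respects the paired design.

## Detection metrics and inference

All proportions (accuracy, stratified accuracy, mixed and component
sensitivity/specificity, false-reassurance rate) carry exact
Clopper–Pearson 95% intervals via the beta-quantile identity; the test
suite checks these against a brute-force binomial tail-inversion oracle
for every (k, n) with n ≤ 30. Accuracy can alternatively carry a seeded
percentile-bootstrap interval. Component specificities are computed and
reported even where the original tables print only sensitivities.

Cohen's κ is the unweighted six-category form against the reference; its
CI uses the Fleiss–Cohen–Everitt asymptotic variance with normal
quantiles (the published CI method is unstated; this is the standard
auditable choice, cross-checked against statsmodels in tests). The exact
McNemar test doubles the smaller binomial tail of the discordant pairs
and caps at 1 — the only standard variant consistent with the published
p = 0.267 given correct totals 41 vs 36; chi-square (with/without
continuity correction) and mid-p variants are provided for comparison.
The false-reassurance exact binomial test takes its null rate p0 as an
explicit parameter: the published p = 0.0015 cannot be reproduced because
no null rate is stated (p0 = 0 is degenerate; conventional choices
0.02–0.05 give one-sided p between 0.0009 and 0.0298), so no default is
hard-coded beyond p0 = 0 for the descriptive rate.

Post-hoc power uses the arcsine effect size h = 2·asin√p₁ − 2·asin√p₂
and the one-tail approximation Φ(|h|·√(n/2) − z₁₋α/₂) with n = 50 per
group — the standard unpaired two-proportion form, reproducing the
published 0.22 and 0.24. Applied to a paired design it is a deliberate
convention-following approximation, not an exact paired power.

## The canonical cohort

No case-level data accompany the study; only marginals are printed. The
package embeds one hand-constructed 50-case assignment satisfying all of
them simultaneously: the reference distribution 24/8/6/5/4/3; each
evaluator's correct total (41, 36), mixed true/false positives (23/7,
15/3), false-normal counts (0, 4), mixed-as-single count (5 for the AI),
component false negatives (metabolic 1 vs 4, respiratory 0 vs 4 on
denominators 35 and 34); κ values rounding (half-up, 2 dp) to 0.73 and
0.63; and the paired discordance (9, 4) — itself not printed but forced
by the correct totals (b − c = 5) and the exact McNemar p = 0.267, since
2·P(X ≤ 4 | Bin(13, ½)) = 2186/8192 ≈ 0.2669 and no other (b, c) works.
Case-level pairing realizes both-correct 32 / physician-only 9 / AI-only
4 / both-wrong 5.

Cells not pinned by any printed count (e.g. which single category the
physician's one missed mixed case received, or how wrong cases pair
across evaluators) are fixed arbitrarily and documented in the fixture
source. The AI evaluator's component flags are the union of those implied
by its predicted category and the reference components — except its four
false-reassurance cases, which carry no components — realizing the
printed component false-negative counts exactly while leaving the
(unprinted) component specificities at natural values. The physician's
flags follow the predicted category. `verify_constraints` re-checks the
complete constraint set and returns an itemized violation list; the test
suite asserts it is empty, and perturbation tests confirm single flips
are caught. If fuller data are ever published the fixture should simply
be replaced.

Consequences of reconstruction: quantities determined by the marginals
(all table values, κ, McNemar, mean harms, Δ = 0.12, h, power) are
reproduced exactly. Quantities depending on the unprinted case-level
pairing are not: the package's exact Wilcoxon on the fixture gives
p ≈ 0.014 (published: 0.026) and the seeded bootstrap CI ≈ (0.034,
0.219) (published: 0.032–0.220) — same conclusions, different digits —
so tests assert only significance and bracketing for these.

## Synthetic cohorts

The generator abstracts an evaluator as (i) reference-conditioned
confusion rows and (ii) Bernoulli component detection (hit rate when a
component is present, false-flag rate when absent). Reference categories
are drawn i.i.d. from a configurable distribution; evaluators are sampled
independently given the reference (no residual inter-evaluator
correlation — the study gives no pairing model, so correlated behavior is
covered by the fixture instead); component flags are sampled
independently of the predicted category given the reference components,
mirroring the independent component coding. Same seed + config →
byte-identical cohorts. Defaults for study-shaped simulations come from
`profile_from_fixture`, the empirical profile of the canonical cohort.
Parameter recovery is tested at n = 50,000 with tolerances set from the
binomial standard error (±0.02 ≳ 6 SE for the mixed-sensitivity check).
What passing these tests shows is that the *estimators* are consistent
under the model's assumptions — not that real evaluators behave like
independent confusion rows; real raters drift, correlate, and see
non-i.i.d. case mixes.

## Numerical choices

- Rounding for display mirrors the published tables: proportions 2 dp,
  p-values 3 dp, harm means 3 dp; κ constraint checks use half-up
  rounding. Report JSON serializes floats at 6 dp for byte-stable reruns.
- Exact paths (McNemar, Wilcoxon, Clopper–Pearson) are all dual-routed in
  tests against independent enumeration/inversion oracles.
- Degenerate inputs fail loudly: all-zero Wilcoxon differences raise (a
  pipeline-level comparison of identical evaluators reports a null
  p-value rather than a silent 1), empty strata raise `EmptyStratumError`,
  κ with single-category marginals raises, invalid generator
  distributions are rejected before any sampling.
- Test problem sizes (full CP sweep at n ≤ 30, sign enumeration at ≤ 12
  differences, one 50,000-case recovery draw) keep the whole suite in a
  few seconds while still over-covering the n = 50 regime the package
  targets.

## Limitations

Keyword harmonization breaks on narratives that name a compensating
disorder explicitly without compensation vocabulary. Harm weights are a
modeling instrument — ordinal severity made numeric — not estimates of
true clinical harm; conclusions should be checked for robustness across
weight choices (linearity makes this cheap). The canonical cohort is one
of many datasets consistent with the published marginals; only
marginal-determined quantities are exact. The power formula ignores
pairing. No ROC/AUC machinery: evaluators emit hard labels.
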