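"""Full-cohort evaluation pipeline and report rendering.

`run_pipeline` orchestrates every analysis on a cohort — accuracy with
McNemar-paired comparison, chance-corrected agreement, complexity-
stratified and component-level detection, false reassurance, the
harm-weighted comparison, and post-hoc power — into one nested report
(JSON-serializable) plus CSV tables mirroring the study's table layout.
Identical inputs, configuration and seed yield byte-identical JSON.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .categories import CATEGORY_ORDER
from .cohort import CohortDataset
from .harm import DEFAULT_WEIGHTS, HarmWeights, bootstrap_mean_difference
from .inference import (
    cohens_h,
    mcnemar_chi2,
    mcnemar_exact,
    mcnemar_midp,
    paired_correctness_table,
    posthoc_power_two_proportions,
)
from .metrics import (
    cohens_kappa,
    complexity_stratified_accuracy,
    component_detection,
    confusion_matrix,
    false_reassurance,
    mixed_detection,
    overall_accuracy,
)

logger = logging.getLogger("abgeval")

_MCNEMAR = {"exact": mcnemar_exact, "chi2": mcnemar_chi2, "midp": mcnemar_midp}


def _pkg_version() -> str:
    try:
        return version("abgeval")
    except PackageNotFoundError:  # pragma: no cover - editable-install edge
        return "unknown"


@dataclass
class RunConfig:
    """Everything tunable about a pipeline run."""

    weights: HarmWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    bootstrap_iterations: int = 5000
    seed: int = 0
    alpha: float = 0.05
    false_reassurance_null: float = 0.0
    mcnemar_variant: str = "exact"
    wilcoxon_zero_method: str = "wilcox"
    evaluator_pairs: list[tuple[str, str]] | None = None  # None = all pairs

    def __post_init__(self) -> None:
        if self.mcnemar_variant not in _MCNEMAR:
            raise ValueError(
                f"mcnemar_variant must be one of {sorted(_MCNEMAR)}"
            )

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "weights" in payload:
            payload["weights"] = HarmWeights(**payload["weights"])
        if payload.get("evaluator_pairs"):
            payload["evaluator_pairs"] = [tuple(p) for p in payload["evaluator_pairs"]]
        return cls(**payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _r(x: float, nd: int = 6) -> float:
    """Fixed-precision serialization keeps report JSON byte-stable."""
    return round(float(x), nd)


def _detection_dict(m) -> dict:
    return {
        "numerator": m.numerator,
        "denominator": m.denominator,
        "estimate": _r(m.estimate),
        "ci_low": _r(m.ci_low),
        "ci_high": _r(m.ci_high),
    }


def run_pipeline(dataset: CohortDataset, config: RunConfig | None = None) -> dict:
    """Run every analysis and return the nested report."""
    config = config or RunConfig()
    logger.info(
        "abgeval %s: evaluating cohort (n=%d, provenance=%s) with seed=%d, B=%d",
        _pkg_version(), dataset.n, dataset.provenance, config.seed,
        config.bootstrap_iterations,
    )

    report: dict = {
        "meta": {
            "package_version": _pkg_version(),
            "n_cases": dataset.n,
            "provenance": dataset.provenance,
            "evaluators": list(dataset.evaluators),
            "seed": config.seed,
            "bootstrap_iterations": config.bootstrap_iterations,
            "alpha": config.alpha,
            "false_reassurance_null": config.false_reassurance_null,
            "mcnemar_variant": config.mcnemar_variant,
            "wilcoxon_zero_method": config.wilcoxon_zero_method,
            "harm_weights": {
                "false_reassurance": _r(config.weights.w_false_reassurance),
                "mixed_as_single": _r(config.weights.w_mixed_as_single),
                "other": _r(config.weights.w_other),
            },
        },
        "accuracy": {},
        "agreement": {},
        "stratified_accuracy": {},
        "mixed_detection": {},
        "component_detection": {},
        "false_reassurance": {},
        "confusion_matrices": {},
        "paired": {},
    }

    for ev in dataset.evaluators:
        acc = overall_accuracy(dataset, ev, alpha=config.alpha)
        report["accuracy"][ev] = _detection_dict(acc)
        kap = cohens_kappa(dataset, ev, alpha=config.alpha)
        report["agreement"][ev] = {
            "kappa": _r(kap.kappa),
            "ci_low": _r(kap.ci_low),
            "ci_high": _r(kap.ci_high),
            "observed_agreement": _r(kap.observed_agreement),
            "expected_agreement": _r(kap.expected_agreement),
        }
        mixed_stratum, single_stratum = complexity_stratified_accuracy(dataset, ev)
        report["stratified_accuracy"][ev] = {
            "mixed": _detection_dict(mixed_stratum),
            "non_mixed": _detection_dict(single_stratum),
        }
        sens, spec = mixed_detection(dataset, ev)
        report["mixed_detection"][ev] = {
            "sensitivity": _detection_dict(sens),
            "specificity": _detection_dict(spec),
        }
        comps = component_detection(dataset, ev)
        report["component_detection"][ev] = {
            comp: {
                "sensitivity": _detection_dict(pair[0]),
                "specificity": _detection_dict(pair[1]),
            }
            for comp, pair in comps.items()
        }
        fr = false_reassurance(dataset, ev, config.false_reassurance_null)
        report["false_reassurance"][ev] = {
            "rate": _detection_dict(fr.rate),
            "null_rate": _r(fr.p0),
            "p_two_sided": _r(fr.p_value_two_sided),
            "p_greater": _r(fr.p_value_greater),
        }
        counts, props = confusion_matrix(dataset, ev)
        report["confusion_matrices"][ev] = {
            "order": [c.value for c in CATEGORY_ORDER],
            "counts": counts.tolist(),
            "row_proportions": [[_r(x, 4) for x in row] for row in props],
        }

    pairs = config.evaluator_pairs or list(
        itertools.combinations(dataset.evaluators, 2)
    )
    if len(dataset.evaluators) < 2:
        logger.warning("single evaluator: paired analyses skipped")
        pairs = []
    for ev_a, ev_b in pairs:
        table = paired_correctness_table(dataset, ev_a, ev_b)
        mcnemar_p = _MCNEMAR[config.mcnemar_variant](table)
        acc_a = report["accuracy"][ev_a]["estimate"]
        acc_b = report["accuracy"][ev_b]["estimate"]
        h = cohens_h(acc_a, acc_b)
        power = posthoc_power_two_proportions(h, dataset.n, config.alpha)
        harm = bootstrap_mean_difference(
            dataset, ev_a, ev_b, config.weights,
            n_bootstrap=config.bootstrap_iterations, seed=config.seed,
            zero_method=config.wilcoxon_zero_method,
        )
        report["paired"][f"{ev_a}__vs__{ev_b}"] = {
            "correctness_table": {
                "both_correct": table.both_correct,
                f"{ev_a}_only_correct": table.a_only_correct,
                f"{ev_b}_only_correct": table.b_only_correct,
                "both_wrong": table.both_wrong,
            },
            "mcnemar_p": _r(mcnemar_p),
            "cohens_h": _r(h),
            "posthoc_power": _r(power.power),
            "harm": {
                "mean_harm_a": _r(harm.mean_harm_a),
                "mean_harm_b": _r(harm.mean_harm_b),
                "mean_difference_b_minus_a": _r(harm.mean_difference),
                "wilcoxon_p": (
                    _r(harm.wilcoxon_p) if harm.wilcoxon_p is not None else None
                ),
                "bootstrap_ci_low": _r(harm.ci_low),
                "bootstrap_ci_high": _r(harm.ci_high),
                "n_bootstrap": harm.n_bootstrap,
                "seed": harm.seed,
            },
        }
    return report


# ---------------------------------------------------------------------------
# rendering

def _fmt_metric(d: dict, pct: bool = False) -> str:
    est = d["estimate"]
    shown = f"{est * 100:.0f}%" if pct else f"{est:.2f}"
    return f"{d['numerator']}/{d['denominator']} ({shown})"


def report_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Render the report as DataFrames mirroring the study's tables."""
    evaluators = report["meta"]["evaluators"]
    acc_rows = [
        {
            "evaluator": ev,
            "correct": _fmt_metric(report["accuracy"][ev], pct=True),
            "incorrect": (
                f"{report['accuracy'][ev]['denominator'] - report['accuracy'][ev]['numerator']}"
                f"/{report['accuracy'][ev]['denominator']}"
            ),
            "kappa": f"{report['agreement'][ev]['kappa']:.2f}",
        }
        for ev in evaluators
    ]
    detection_rows = []
    for metric, getter in [
        ("Mixed sensitivity", lambda ev: report["mixed_detection"][ev]["sensitivity"]),
        ("Mixed specificity", lambda ev: report["mixed_detection"][ev]["specificity"]),
        ("Metabolic sensitivity", lambda ev: report["component_detection"][ev]["metabolic"]["sensitivity"]),
        ("Respiratory sensitivity", lambda ev: report["component_detection"][ev]["respiratory"]["sensitivity"]),
        ("False-normal in mixed", lambda ev: report["false_reassurance"][ev]["rate"]),
    ]:
        detection_rows.append(
            {"metric": metric, **{ev: _fmt_metric(getter(ev)) for ev in evaluators}}
        )
    harm_rows = []
    for pair, block in report["paired"].items():
        harm = block["harm"]
        harm_rows.append(
            {
                "pair": pair,
                "mean_harm_a": f"{harm['mean_harm_a']:.3f}",
                "mean_harm_b": f"{harm['mean_harm_b']:.3f}",
                "mean_difference": f"{harm['mean_difference_b_minus_a']:.2f}",
                "bootstrap_95ci": f"{harm['bootstrap_ci_low']:.3f}-{harm['bootstrap_ci_high']:.3f}",
                "wilcoxon_p": (
                    f"{harm['wilcoxon_p']:.3f}"
                    if harm["wilcoxon_p"] is not None
                    else "n/a"
                ),
                "mcnemar_p": f"{block['mcnemar_p']:.3f}",
                "posthoc_power": f"{block['posthoc_power']:.2f}",
            }
        )
    tables = {
        "accuracy": pd.DataFrame(acc_rows),
        "detection": pd.DataFrame(detection_rows),
        "harm": pd.DataFrame(harm_rows),
    }
    for ev in evaluators:
        block = report["confusion_matrices"][ev]
        tables[f"confusion_{ev}"] = pd.DataFrame(
            block["counts"],
            index=[f"pred_{c}" for c in block["order"]],
            columns=[f"ref_{c}" for c in block["order"]],
        )
    return tables


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write the JSON report and CSV tables; returns the JSON path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, frame in report_tables(report).items():
        frame.to_csv(
            outdir / f"{name}.csv", index=name.startswith("confusion_")
        )
    logger.info("report written to %s", outdir)
    return json_path
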