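"""End-to-end orchestration: simulate -> quantify -> analyze -> report.

The pipeline generates (or loads) a matched cohort, computes breast-wise
kinetic measures (full-image mode routes every subject through the
quantification module; measures-only mode consumes generator output
directly), fits the conditional-logistic and ROC models, and writes a
machine-readable results JSON plus a human-readable report whose numbers
are taken verbatim from the JSON.  A fixed configuration and seed
reproduce the results byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import matched_stats as ms
from .cohort import MatchedCohort
from .kinetics import DEFAULT_THRESHOLDS, KineticThresholds, pair_change_class
from .phantom import CohortSpec, make_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "analyze_cohort",
    "summarize_pairs",
    "render_report",
    "DEFAULT_CLR_MODELS",
    "DEFAULT_AUC_MODELS",
    "DEFAULT_LRT_PAIRS",
    "DEFAULT_OR_UNITS",
    "PHANTOM_OR_UNITS",
]

log = logging.getLogger("parenkin.pipeline")

# conditional-logistic model battery (name -> covariates)
DEFAULT_CLR_MODELS: dict[str, list[str]] = {
    "wisv_univariate": ["wisv"],
    "serv_univariate": ["serv_cm3"],
    "wisv_serv": ["wisv", "serv_cm3"],
    "base_wisv_serv": ["menopausal", "family_history", "density", "wisv", "serv_cm3"],
    "bpe_univariate": ["bpe_pct"],
    "wisv_serv_bpe": ["wisv", "serv_cm3", "bpe_pct"],
}

# unconditional logistic models scored by ROC/AUC and LOOCV
DEFAULT_AUC_MODELS: dict[str, list[str]] = {
    "M1": ["wisv"],
    "M2": ["serv_cm3"],
    "M3": ["wisv", "serv_cm3"],
    "M4": ["bpe_pct"],
    "M5": ["wisv", "serv_cm3", "bpe_pct"],
}

# (nested, full) model comparisons for the likelihood-ratio test
DEFAULT_LRT_PAIRS: list[tuple[str, str]] = [
    ("M1", "M3"),
    ("M2", "M3"),
    ("M3", "M5"),
    ("M4", "M5"),
]

# odds-ratio reporting units on the clinical measure scale:
# WISV per 0.01 unit, SER volume per 100 cm^3, BPE% per 20 percentage points
DEFAULT_OR_UNITS: dict[str, float] = {"wisv": 0.01, "serv_cm3": 100.0, "bpe_pct": 20.0}

# phantom-scale units (desk-scale grids give SER volumes of order 0.1 cm^3)
PHANTOM_OR_UNITS: dict[str, float] = {"wisv": 0.01, "serv_cm3": 0.1, "bpe_pct": 20.0}

PAIR_MEASURES = ["wisv", "serv_cm3", "bpe_pct"]
SPEARMAN_PAIRS = [
    ("wisv", "serv_cm3"),
    ("wisv", "bpe_pct"),
    ("serv_cm3", "bpe_pct"),
    ("wisv", "density"),
    ("serv_cm3", "density"),
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path = "parenkin-run"
    mode: str = "measures-only"  # or "full-image"
    n_pairs: int = 51
    seed: int = 0
    null_effect: bool = False
    thresholds: KineticThresholds = field(default_factory=KineticThresholds)
    or_units: dict[str, float] | None = None  # default depends on mode
    clr_models: dict[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_CLR_MODELS)
    )
    auc_models: dict[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_AUC_MODELS)
    )
    lrt_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_LRT_PAIRS)
    )
    pair_measures: list[str] = field(default_factory=lambda: list(PAIR_MEASURES))
    cohort_spec: CohortSpec | None = None  # overrides n_pairs/seed/null_effect

    def resolved_units(self) -> dict[str, float]:
        if self.or_units is not None:
            return dict(self.or_units)
        return dict(PHANTOM_OR_UNITS if self.mode == "full-image" else DEFAULT_OR_UNITS)

    def to_jsonable(self) -> dict:
        d = {
            "mode": self.mode,
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "null_effect": self.null_effect,
            "thresholds": dataclasses.asdict(self.thresholds),
            "or_units": self.resolved_units(),
            "clr_models": self.clr_models,
            "auc_models": self.auc_models,
            "lrt_pairs": [list(p) for p in self.lrt_pairs],
            "pair_measures": self.pair_measures,
        }
        return d


def summarize_pairs(
    cohort: MatchedCohort, measure: str, band: float = 0.15
) -> dict[str, int]:
    """Counts of matched pairs by case-vs-control change class for a measure."""
    counts = {"greater15": 0, "less15": 0, "within15": 0}
    for p in cohort.pairs:
        if measure not in p.case.measures or measure not in p.control.measures:
            raise ValueError(f"measure {measure!r} missing from cohort")
        cls = pair_change_class(
            p.case.measures[measure], p.control.measures[measure], band=band
        )
        counts[cls] += 1
    return counts


def _clr_results(cohort, models, units) -> dict:
    out = {}
    for name, covs in models.items():
        try:
            fit = ms.clr_fit(cohort, covs, units=units)
        except ValueError as exc:
            out[name] = {"error": str(exc)}
            continue
        out[name] = {
            "converged": fit.converged,
            "loglik": float(fit.loglik),
            "n_pairs": fit.n_pairs,
            "covariates": {
                c: {
                    "coef": float(fit.coef[j]),
                    "se": float(fit.se[j]),
                    "unit": float(fit.units[j]),
                    "or": float(fit.odds_ratios[j]),
                    "or_ci_low": float(fit.or_ci_low[j]),
                    "or_ci_high": float(fit.or_ci_high[j]),
                    "p_value": float(fit.p_values[j]),
                }
                for j, c in enumerate(fit.covariates)
            },
        }
        if fit.message:
            out[name]["message"] = fit.message
    return out


def _auc_results(table, models) -> tuple[dict, dict]:
    out = {}
    fits = {}
    for name, covs in models.items():
        fit = ms.logistic_fit(table, covs)
        fits[name] = fit
        roc = ms.auc(fit.fitted, fit.labels)
        loo = ms.loocv_auc(table, covs)
        out[name] = {
            "covariates": list(covs),
            "converged": fit.converged,
            "loglik": float(fit.loglik),
            "auc": float(roc.auc),
            "auc_ci": [float(roc.ci_low), float(roc.ci_high)],
            "loocv_auc": float(loo.auc),
            "loocv_auc_ci": [float(loo.ci_low), float(loo.ci_high)],
            "loocv_flagged_folds": int(loo.n_flagged_folds),
        }
    return out, fits


def analyze_cohort(
    cohort: MatchedCohort,
    thresholds: KineticThresholds = DEFAULT_THRESHOLDS,
    clr_models: dict[str, list[str]] | None = None,
    auc_models: dict[str, list[str]] | None = None,
    lrt_pairs: list[tuple[str, str]] | None = None,
    or_units: dict[str, float] | None = None,
    pair_measures: list[str] | None = None,
) -> dict:
    """Run the full statistical battery on a matched cohort.

    Models that fail identifiability checks are reported with an ``error``
    entry rather than aborting the whole analysis.
    """
    clr_models = clr_models if clr_models is not None else DEFAULT_CLR_MODELS
    auc_models = auc_models if auc_models is not None else DEFAULT_AUC_MODELS
    lrt_pairs = lrt_pairs if lrt_pairs is not None else DEFAULT_LRT_PAIRS
    or_units = or_units if or_units is not None else DEFAULT_OR_UNITS
    pair_measures = pair_measures if pair_measures is not None else PAIR_MEASURES
    available = set(cohort.measure_names())
    pair_measures = [m for m in pair_measures if m in available]

    table = cohort.to_subject_frame()

    results: dict = {"n_pairs": cohort.n_pairs}
    results["clr"] = _clr_results(cohort, clr_models, or_units)
    auc_out, fits = _auc_results(table, auc_models)
    results["auc"] = auc_out
    results["lrt"] = {}
    for nested, full in lrt_pairs:
        if nested not in fits or full not in fits:
            continue
        try:
            res = ms.lrt(fits[nested], fits[full])
        except ValueError as exc:
            results["lrt"][f"{full}_vs_{nested}"] = {"error": str(exc)}
            continue
        results["lrt"][f"{full}_vs_{nested}"] = {
            "statistic": float(res.statistic),
            "df": int(res.df),
            "p_value": float(res.p_value),
        }
    results["pair_classification"] = {
        m: summarize_pairs(cohort, m, band=thresholds.pair_band) for m in pair_measures
    }
    results["spearman"] = {}
    for a, b in SPEARMAN_PAIRS:
        if a not in table.columns or b not in table.columns:
            continue
        try:
            rho, p = ms.spearman(table[a].to_numpy(), table[b].to_numpy())
        except ValueError:
            continue
        results["spearman"][f"{a}_vs_{b}"] = {"rho": float(rho), "p_value": float(p)}
    return results


def _results_bytes(results: dict) -> bytes:
    return json.dumps(results, sort_keys=True, indent=2).encode()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and write cohort.csv, results.json and report.md.

    Returns the results dictionary (also serialized to ``results.json``).
    Reruns with an identical configuration are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cfg_json = config.to_jsonable()
    cfg_hash = hashlib.sha256(_results_bytes(cfg_json)).hexdigest()
    log.info("stage=simulate mode=%s n_pairs=%d seed=%d", config.mode, config.n_pairs, config.seed)

    if config.cohort_spec is not None:
        cspec = config.cohort_spec
    elif config.null_effect:
        cspec = CohortSpec.null(n_pairs=config.n_pairs, seed=config.seed)
    else:
        cspec = CohortSpec(n_pairs=config.n_pairs, seed=config.seed)
    cohort = make_cohort(cspec, mode=config.mode)
    cohort.to_csv(out_dir / "cohort.csv")

    log.info("stage=analyze n_pairs=%d", cohort.n_pairs)
    results = analyze_cohort(
        cohort,
        thresholds=config.thresholds,
        clr_models=config.clr_models,
        auc_models=config.auc_models,
        lrt_pairs=config.lrt_pairs,
        or_units=config.resolved_units(),
        pair_measures=config.pair_measures,
    )
    results["provenance"] = {
        "seed": config.seed,
        "mode": config.mode,
        "config_sha256": cfg_hash,
    }
    results["config"] = cfg_json

    (out_dir / "results.json").write_bytes(_results_bytes(results))
    (out_dir / "report.md").write_text(render_report(results))
    log.info("stage=report out=%s", out_dir)
    return results


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}g}"


def render_report(results: dict) -> str:
    """Human-readable markdown report; every number comes from the results
    dictionary (no recomputation)."""
    lines = ["# Matched case-control kinetics analysis", ""]
    prov = results.get("provenance", {})
    lines.append(
        f"Pairs: {results.get('n_pairs')} | mode: {prov.get('mode', '?')} | "
        f"seed: {prov.get('seed', '?')}"
    )
    lines.append("")

    lines.append("## Conditional logistic regression (odds ratios per declared unit)")
    lines.append("")
    lines.append("| model | covariate | OR | 95% CI | p |")
    lines.append("|---|---|---|---|---|")
    for model, res in sorted(results.get("clr", {}).items()):
        if "error" in res:
            lines.append(f"| {model} | — | — | — | error: {res['error']} |")
            continue
        for cov, r in sorted(res["covariates"].items()):
            ci = f"({_fmt(r['or_ci_low'])}, {_fmt(r['or_ci_high'])})"
            lines.append(
                f"| {model} | {cov} | {_fmt(r['or'])} | {ci} | {_fmt(r['p_value'])} |"
            )
    lines.append("")

    lines.append("## ROC / AUC (unconditional logistic models)")
    lines.append("")
    lines.append("| model | covariates | AUC (95% CI) | LOOCV AUC (95% CI) |")
    lines.append("|---|---|---|---|")
    for model, res in sorted(results.get("auc", {}).items()):
        ci = f"({_fmt(res['auc_ci'][0])}, {_fmt(res['auc_ci'][1])})"
        lci = f"({_fmt(res['loocv_auc_ci'][0])}, {_fmt(res['loocv_auc_ci'][1])})"
        lines.append(
            f"| {model} | {'+'.join(res['covariates'])} | {_fmt(res['auc'])} {ci} | "
            f"{_fmt(res['loocv_auc'])} {lci} |"
        )
    lines.append("")

    if results.get("lrt"):
        lines.append("## Likelihood-ratio tests")
        lines.append("")
        lines.append("| comparison | statistic | df | p |")
        lines.append("|---|---|---|---|")
        for name, res in sorted(results["lrt"].items()):
            if "error" in res:
                lines.append(f"| {name} | — | — | error: {res['error']} |")
            else:
                lines.append(
                    f"| {name} | {_fmt(res['statistic'])} | {res['df']} | "
                    f"{_fmt(res['p_value'])} |"
                )
        lines.append("")

    if results.get("pair_classification"):
        lines.append("## Matched-pair change classification (case vs control)")
        lines.append("")
        lines.append("| measure | >15% greater | >15% less | within 15% |")
        lines.append("|---|---|---|---|")
        for m, c in sorted(results["pair_classification"].items()):
            lines.append(
                f"| {m} | {c['greater15']} | {c['less15']} | {c['within15']} |"
            )
        lines.append("")

    if results.get("spearman"):
        lines.append("## Spearman correlations")
        lines.append("")
        lines.append("| pair | rho | p |")
        lines.append("|---|---|---|")
        for name, r in sorted(results["spearman"].items()):
            lines.append(f"| {name} | {_fmt(r['rho'])} | {_fmt(r['p_value'])} |")
        lines.append("")

    return "\n".join(lines)
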