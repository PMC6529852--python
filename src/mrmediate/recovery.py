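"""End-to-end parameter recovery: simulate, analyse, compare to truth.

Runs the full analysis surface against a simulated study whose estimands
are known in closed form:

* two-sample arm — GWAS summary statistics are computed on two
  *independent* cohorts drawn from the same configuration (exposure and
  mediator scans on one, the outcome scan on the other, honouring the
  non-overlapping-samples assumption), then fed through IVW / Egger /
  weighted-median total effects, per-mediator two-step mediation and the
  combined-difference multivariable MR;
* one-sample arm — split-sample allele scores (weights estimated on one
  half, applied to the other) with ratio / multivariable score estimators;
* observational arm — confounder-naive regression mediation on the observed
  (measurement-error-contaminated) mediators.
"""
from __future__ import annotations

from dataclasses import asdict, replace
from typing import Mapping, Sequence

import numpy as np

from .individual_level import (
    Cohort,
    ScoreDefinition,
    build_allele_score,
    multivariable_one_sample_mr,
    observational_mediation,
    observational_total,
    one_sample_mr,
)
from .mr_estimators import MrEstimate, ivw_fixed, mr_egger, weighted_median
from .mvmr_mediation import (
    Effect,
    MediationEstimate,
    combined_difference,
    harmonise_multi,
    mvmr_fit,
    product_indirect,
    proportion_mediated,
)
from .summary_core import harmonise
from .synthetic_data import (
    MEDIATORS,
    SimulationTruth,
    SynthConfig,
    compute_gwas_summaries,
    panel_snp_ids,
    simulate_cohort,
    split_sample,
)


def _child_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(k)]


def two_sample_arm(
    cohort_exposure: Cohort,
    cohort_outcome: Cohort,
    config: SynthConfig,
    seed: int,
    n_boot_median: int = 200,
) -> dict:
    """Summary-statistic pipeline on two independent cohorts."""
    ss_edu = compute_gwas_summaries(cohort_exposure, "education")
    ss_med = {m: compute_gwas_summaries(cohort_exposure, m) for m in MEDIATORS}
    ss_out = compute_gwas_summaries(cohort_outcome, "outcome")
    edu_ids = panel_snp_ids(config, "education")

    h_total = harmonise(ss_edu.subset(edu_ids), ss_out)
    total = ivw_fixed(h_total)
    egger = mr_egger(h_total)
    wmedian = weighted_median(h_total, n_boot=n_boot_median, seed=seed)

    edu_on_mediator = {
        m: ivw_fixed(harmonise(ss_edu.subset(edu_ids), ss_med[m])) for m in MEDIATORS
    }

    mediation: dict[str, MediationEstimate] = {}
    for m in MEDIATORS:
        med_ids = panel_snp_ids(config, m)
        union = edu_ids + med_ids
        multi = harmonise_multi([ss_edu, ss_med[m]], ss_out, snp_ids=union)
        fit = mvmr_fit(multi, subtract_exposure_noise=True)
        b = fit.effect(m)
        a = edu_on_mediator[m]
        indirect = product_indirect(Effect(a.beta, a.se), b)
        prop = proportion_mediated(indirect, Effect(total.beta, total.se))
        mediation[m] = MediationEstimate(
            total=Effect(total.beta, total.se), indirect=indirect, proportion=prop,
            method="product_two_step",
            components={"a": Effect(a.beta, a.se), "b": b}, n_snps=len(multi),
        )

    all_ids = [s for t in ("education", *MEDIATORS) for s in panel_snp_ids(config, t)]
    multi_all = harmonise_multi(
        [ss_edu, *(ss_med[m] for m in MEDIATORS)], ss_out, snp_ids=all_ids
    )
    fit_all = mvmr_fit(multi_all, subtract_exposure_noise=True)
    combined = combined_difference(total, fit_all, exposure="education")

    return {
        "total": total, "egger": egger, "weighted_median": wmedian,
        "edu_on_mediator": edu_on_mediator,
        "mediation": mediation, "combined": combined,
        "mvmr_all": fit_all,
    }


def one_sample_arm(cohort: Cohort, config: SynthConfig, seed: int) -> dict:
    """Split-sample allele-score MR on a single cohort.

    Score weights are estimated by GWAS on one random half and the scores
    built and analysed on the other, avoiding winner's-curse-style overlap
    between weight estimation and effect estimation.
    """
    half_w, half_a = split_sample(cohort, 0.5, seed=seed)
    scores: dict[str, np.ndarray] = {}
    for trait, col in [("education", "education")] + [(m, m) for m in MEDIATORS]:
        ids = panel_snp_ids(config, trait)
        gwas = compute_gwas_summaries(half_w, col, snp_ids=ids)
        weights = {r.snp_id: r.beta for r in gwas}
        scores[trait] = build_allele_score(
            half_a, ScoreDefinition(weights, source_label=f"split-half GWAS {trait}")
        )

    total = one_sample_mr(half_a, scores["education"], "education", "outcome")

    mediation: dict[str, MediationEstimate] = {}
    for m in MEDIATORS:
        a_est = one_sample_mr(half_a, scores["education"], "education", m)
        joint = multivariable_one_sample_mr(
            half_a,
            {"education": scores["education"], m: scores[m]},
            ["education", m],
            "outcome",
        )
        b = joint[m]
        indirect = product_indirect(Effect(a_est.beta, a_est.se), b)
        prop = proportion_mediated(indirect, Effect(total.beta, total.se))
        mediation[m] = MediationEstimate(
            total=Effect(total.beta, total.se), indirect=indirect, proportion=prop,
            method="product_two_step",
            components={"a": Effect(a_est.beta, a_est.se), "b": b},
        )

    joint_all = multivariable_one_sample_mr(
        half_a, scores, ["education", *MEDIATORS], "outcome"
    )
    d = joint_all["education"]
    t_eff = Effect(total.beta, total.se)
    point = (t_eff.beta - d.beta) / t_eff.beta
    se = float(np.sqrt((d.se / t_eff.beta) ** 2 + (d.beta * t_eff.se / t_eff.beta**2) ** 2))
    from .mr_estimators import Z95
    from .mvmr_mediation import ProportionEstimate

    combined = MediationEstimate(
        total=t_eff, direct=d,
        indirect=Effect(t_eff.beta - d.beta, float(np.sqrt(t_eff.se**2 + d.se**2))),
        proportion=ProportionEstimate(point, se, point - Z95 * se, point + Z95 * se),
        method="difference_combined",
    )
    return {"total": total, "mediation": mediation, "combined": combined}


def observational_arm(
    cohort: Cohort,
    confounders: Sequence[str] = (),
    n_boot: int = 0,
    seed: int | None = None,
) -> dict:
    """Regression mediation on the observed phenotypes.

    With ``n_boot = 0`` delta-method SEs are used (fast path); otherwise
    nonparametric bootstrap with the given seed.
    """
    kwargs: dict = {"se_method": "delta"} if n_boot == 0 else {
        "se_method": "bootstrap", "n_boot": n_boot, "seed": seed,
    }
    total = observational_total(cohort, "education", "outcome", confounders)
    mediation = {
        m: observational_mediation(
            cohort, "education", [m], "outcome", confounders, **kwargs
        )
        for m in MEDIATORS
    }
    combined = observational_mediation(
        cohort, "education", list(MEDIATORS), "outcome", confounders, **kwargs
    )
    return {"total": total, "mediation": mediation, "combined": combined}


def end_to_end_truth_check(
    config: SynthConfig,
    arms: Sequence[str] = ("two_sample", "one_sample", "observational"),
    n_boot_median: int = 200,
    observational_boot: int = 0,
) -> dict:
    """Simulate, run the requested analysis arms, and report vs truth.

    The exposure-side and outcome-side cohorts of the two-sample arm are
    independent draws; the one-sample and observational arms use the
    exposure-side cohort.
    """
    truth = SimulationTruth.from_config(config)
    s_exp, s_out, s_misc = _child_seeds(config.seed, 3)
    arch = config.seed if config.architecture_seed is None else config.architecture_seed
    cohort_exp, _ = simulate_cohort(replace(config, seed=s_exp, architecture_seed=arch))
    report: dict = {"truth": truth, "config": config}
    if "two_sample" in arms:
        cohort_out, _ = simulate_cohort(replace(config, seed=s_out, architecture_seed=arch))
        report["two_sample"] = two_sample_arm(
            cohort_exp, cohort_out, config, seed=s_misc, n_boot_median=n_boot_median
        )
    if "one_sample" in arms:
        report["one_sample"] = one_sample_arm(cohort_exp, config, seed=s_misc)
    if "observational" in arms:
        report["observational"] = observational_arm(
            cohort_exp, n_boot=observational_boot, seed=s_misc
        )
    return report


def recovery_table(report: Mapping) -> "pd.DataFrame":
    """Flatten a recovery report into estimated-vs-true rows."""
    import pandas as pd

    truth: SimulationTruth = report["truth"]
    rows = []

    def add(arm, quantity, est, se, true):
        rows.append({
            "arm": arm, "quantity": quantity, "estimate": est, "se": se,
            "truth": true, "error": est - true if true is not None else np.nan,
        })

    for arm in ("two_sample", "one_sample", "observational"):
        if arm not in report:
            continue
        r = report[arm]
        add(arm, "total_log_or", r["total"].beta, r["total"].se, truth.true_total)
        for m, est in r["mediation"].items():
            add(arm, f"proportion_{m}", est.proportion.point, est.proportion.se,
                truth.true_proportion[m])
        add(arm, "proportion_combined", r["combined"].proportion.point,
            r["combined"].proportion.se, truth.true_proportion_combined)
        if arm == "two_sample":
            add(arm, "egger_log_or", r["egger"].beta, r["egger"].se, truth.true_total)
            add(arm, "weighted_median_log_or", r["weighted_median"].beta,
                r["weighted_median"].se, truth.true_total)
            for m, est in r["edu_on_mediator"].items():
                add(arm, f"edu_on_{m}_sd", est.beta, est.se, report["config"].theta[m])
    return pd.DataFrame(rows)
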