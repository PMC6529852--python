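"""Config-driven orchestration of the analysis arms, tables and reports.

Configs are plain YAML mappings (see README for the schema). Every output
table carries a provenance header (package version, config hash, seed) and
has a machine-readable JSON twin; odds ratios and proportions are rendered
in the conventional ``0.63 (0.60 to 0.67)`` / ``18% (13% to 23%)`` styles.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .individual_level import Cohort, ScoreDefinition, build_allele_score, one_sample_mr, observational_mediation
from .mr_estimators import MrEstimate, estimate_total_effect, serialise_estimates
from .mvmr_mediation import MediationEstimate, combined_difference, harmonise_multi, mvmr_fit, serialise_mediation, two_step_mediation
from .recovery import end_to_end_truth_check, recovery_table
from .summary_core import SummarySet, clump, read_ld_matrix, read_summary_stats, rescale_per_sd
from .synthetic_data import SynthConfig, simulate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration (exit code 2)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (exit code 3)."""


class EstimationError(RuntimeError):
    """An estimator failed on otherwise valid inputs (exit code 4)."""


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _provenance_lines(cfg: Mapping) -> list[str]:
    seed = cfg.get("seed", "NA")
    return [
        f"# mrmediate {__version__}",
        f"# config_hash {config_hash(cfg)}",
        f"# seed {seed}",
    ]


def _write_table(df: pd.DataFrame, path: Path, cfg: Mapping) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(cfg)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def format_or(beta: float, se: float) -> str:
    """Render a log-odds estimate as ``OR (low to high)`` with 2 decimals."""
    from .mr_estimators import Z95

    return (
        f"{np.exp(beta):.2f} "
        f"({np.exp(beta - Z95 * se):.2f} to {np.exp(beta + Z95 * se):.2f})"
    )


def format_proportion(point: float, ci_low: float, ci_high: float) -> str:
    """Render a proportion as whole percents, ``18% (13% to 23%)``."""
    return f"{point * 100:.0f}% ({ci_low * 100:.0f}% to {ci_high * 100:.0f}%)"


def parse_or(rendered: str) -> tuple[float, float]:
    """Invert :func:`format_or`: recover (beta, se) from the rendered string."""
    from .mr_estimators import Z95

    head, rest = rendered.split(" (")
    low, high = rest.rstrip(")").split(" to ")
    beta = np.log(float(head))
    se = (np.log(float(high)) - np.log(float(low))) / (2 * Z95)
    return float(beta), float(se)


def render_report(bundle: Mapping) -> str:
    """Human-readable summary of a results bundle."""
    if not bundle:
        raise ValueError("empty results bundle")
    lines: list[str] = []
    for section, content in bundle.items():
        lines.append(f"== {section} ==")
        if isinstance(content, pd.DataFrame):
            lines.append(content.to_string(index=False))
        elif isinstance(content, MrEstimate):
            lines.append(f"{content.method}: OR {format_or(content.beta, content.se)} "
                         f"[n_snps={content.n_snps}, p={content.pvalue:.3g}]")
        elif isinstance(content, MediationEstimate):
            p = content.proportion
            lines.append(
                f"{content.method}: proportion mediated "
                f"{format_proportion(p.point, p.ci_low, p.ci_high)}"
            )
        else:
            lines.append(str(content))
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# two-sample run
# ---------------------------------------------------------------------------

def _load_panel(entry: Mapping, cfg: Mapping) -> tuple[SummarySet, list[str]]:
    if "path" not in entry or "name" not in entry:
        raise ConfigError(f"panel entry needs 'name' and 'path': {entry}")
    try:
        sset = read_summary_stats(
            entry["path"], column_map=entry.get("column_map"), trait_name=entry["name"]
        )
    except (OSError, ValueError) as exc:
        raise DataError(f"panel {entry['name']!r}: {exc}") from exc
    if entry.get("sd"):
        sset = rescale_per_sd(sset, float(entry["sd"]))
    clump_cfg = cfg.get("clump")
    if clump_cfg and entry.get("clump", True) and not entry.get("instruments"):
        ld = read_ld_matrix(clump_cfg["ld_matrix"], clump_cfg["positions"])
        sset_inst = clump(
            sset, ld,
            r2_threshold=float(clump_cfg.get("r2", 0.001)),
            window_kb=int(clump_cfg.get("window_kb", 10_000)),
        )
        instruments = sset_inst.snp_ids
    elif entry.get("instruments"):
        instruments = [
            line.strip() for line in open(entry["instruments"]) if line.strip()
        ]
    else:
        instruments = sset.snp_ids
    return sset, instruments


def run_two_sample(cfg: Mapping, output_dir: str | Path | None = None) -> dict:
    """Total effects, per-mediator two-step mediation, combined difference."""
    for key in ("exposure", "outcome"):
        if key not in cfg:
            raise ConfigError(f"two-sample config missing {key!r} section")
    seed = cfg.get("seed")
    if seed is None:
        raise ConfigError("two-sample config requires a seed (weighted median bootstrap)")
    exposure, edu_instruments = _load_panel(cfg["exposure"], cfg)
    outcome, _ = _load_panel(dict(cfg["outcome"], clump=False), cfg)
    hopts = {}
    if "palindrome_policy" in cfg:
        hopts["palindrome_policy"] = cfg["palindrome_policy"]

    try:
        methods = cfg.get("estimators", ["ivw_fixed", "egger", "weighted_median"])
        estimates = []
        for method in methods:
            opts = {}
            if method == "weighted_median":
                opts = {"n_boot": int(cfg.get("n_boot", 1000)), "seed": int(seed)}
            estimates.append(
                estimate_total_effect(
                    exposure.subset(edu_instruments), outcome, method=method,
                    harmonise_options=hopts, **opts,
                )
            )
        total = estimates[0]

        mediation_rows = []
        mediator_panels = []
        for entry in cfg.get("mediators", []):
            med_set, med_instruments = _load_panel(entry, cfg)
            mediator_panels.append((med_set, med_instruments))
            est = two_step_mediation(
                exposure, med_set, outcome,
                edu_instruments=edu_instruments,
                mediator_instruments=med_instruments,
                harmonise_options=hopts,
            )
            mediation_rows.append((entry["name"], est))
        combined = None
        if len(mediator_panels) > 1:
            union = list(dict.fromkeys(
                edu_instruments + [s for _, ids in mediator_panels for s in ids]
            ))
            multi = harmonise_multi(
                [exposure] + [m for m, _ in mediator_panels], outcome,
                snp_ids=union, **hopts,
            )
            combined = combined_difference(total, mvmr_fit(multi), exposure.trait_name)
            mediation_rows.append(("all_mediators", combined))
    except (ValueError, ZeroDivisionError, np.linalg.LinAlgError) as exc:
        raise EstimationError(f"two-sample estimation failed: {exc}") from exc

    est_table = serialise_estimates(estimates, exposure.trait_name, outcome.trait_name)
    med_table = serialise_mediation(mediation_rows, exposure.trait_name, outcome.trait_name)
    bundle = {
        "estimates": est_table,
        "mediation": med_table,
    }
    if output_dir is not None:
        out = Path(output_dir)
        _write_table(est_table, out / "estimates.tsv", cfg)
        _write_table(med_table, out / "mediation.tsv", cfg)
        with open(out / "results.json", "w") as fh:
            json.dump(
                {
                    "estimates": est_table.to_dict(orient="records"),
                    "mediation": med_table.to_dict(orient="records"),
                    "provenance": {"version": __version__, "config_hash": config_hash(cfg), "seed": seed},
                },
                fh, indent=2, default=float,
            )
        with open(out / "report.txt", "w") as fh:
            fh.write(render_report(bundle))
    return bundle


# ---------------------------------------------------------------------------
# one-sample run
# ---------------------------------------------------------------------------

def _load_cohort(cfg: Mapping) -> Cohort:
    section = cfg.get("cohort")
    if not section:
        raise ConfigError("one-sample config missing 'cohort' section")
    try:
        pheno = pd.read_csv(section["phenotypes"], sep="\t")
        dosages = pd.read_csv(section["dosages"], sep="\t")
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot read cohort: {exc}") from exc
    snp_ids = list(dosages.columns)
    return Cohort(dosages.to_numpy(dtype=np.float32), pheno, snp_ids)


def run_one_sample(cfg: Mapping, output_dir: str | Path | None = None) -> dict:
    """Allele-score MR totals and observational-style bootstrap mediation."""
    seed = cfg.get("seed")
    if seed is None:
        raise ConfigError("one-sample config requires a seed (bootstrap)")
    cohort = _load_cohort(cfg)
    roles = cfg.get("columns", {})
    exposure_col = roles.get("exposure", "education")
    outcome_col = roles.get("outcome", "outcome")
    covariates = roles.get("covariates", [])
    scores_cfg = cfg.get("scores", {})
    if exposure_col not in cohort.phenotypes.columns:
        raise DataError(f"exposure column {exposure_col!r} absent from cohort")

    try:
        rows = []
        score_def = _read_score(scores_cfg.get(exposure_col) or scores_cfg.get("exposure"))
        score = build_allele_score(cohort, score_def)
        total = one_sample_mr(cohort, score, exposure_col, outcome_col, covariates)
        rows.append(("total", total))
        med_rows = []
        mediators = roles.get("mediators", [])
        for m in mediators:
            est = observational_mediation(
                cohort, exposure_col, [m], outcome_col, covariates,
                n_boot=int(cfg.get("n_boot", 1000)), seed=int(seed),
            )
            med_rows.append((m, est))
        if len(mediators) > 1:
            scale = "risk_difference" if cfg.get("risk_difference") else "logit"
            est = observational_mediation(
                cohort, exposure_col, mediators, outcome_col, covariates,
                n_boot=int(cfg.get("n_boot", 1000)), seed=int(seed), scale=scale,
            )
            med_rows.append(("all_mediators", est))
    except (ValueError, KeyError) as exc:
        raise EstimationError(f"one-sample estimation failed: {exc}") from exc

    est_table = serialise_estimates([e for _, e in rows], exposure_col, outcome_col)
    med_table = serialise_mediation(med_rows, exposure_col, outcome_col)
    bundle = {"estimates": est_table, "mediation": med_table}
    if output_dir is not None:
        out = Path(output_dir)
        _write_table(est_table, out / "one_sample_estimates.tsv", cfg)
        _write_table(med_table, out / "one_sample_mediation.tsv", cfg)
        with open(out / "one_sample_results.json", "w") as fh:
            json.dump(
                {
                    "estimates": est_table.to_dict(orient="records"),
                    "mediation": med_table.to_dict(orient="records"),
                    "provenance": {"version": __version__, "config_hash": config_hash(cfg), "seed": seed},
                },
                fh, indent=2, default=float,
            )
    return bundle


def _read_score(entry) -> ScoreDefinition:
    if entry is None:
        raise ConfigError("missing score definition for the exposure")
    df = pd.read_csv(entry["path"], sep="\t")
    weights = dict(zip(df["SNP"], df["WEIGHT"].astype(float)))
    alleles = dict(zip(df["SNP"], df["EA"])) if "EA" in df.columns else {}
    return ScoreDefinition(weights, entry.get("label", ""), alleles)


# ---------------------------------------------------------------------------
# simulate / recover
# ---------------------------------------------------------------------------

def synth_config_from_mapping(cfg: Mapping, seed: int | None = None) -> SynthConfig:
    fields = {f.name for f in dataclasses.fields(SynthConfig)}
    kwargs = {k: v for k, v in cfg.items() if k in fields}
    if "maf_range" in kwargs:
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    try:
        return SynthConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc


def run_simulate(cfg: Mapping, output_dir: str | Path, seed: int | None = None) -> None:
    config = synth_config_from_mapping(cfg.get("simulation", cfg), seed=seed)
    cohort, truth = simulate_cohort(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    pd.DataFrame(cohort.genotypes, columns=cohort.snp_ids).to_csv(
        out / "dosages.tsv", sep="\t", index=False
    )
    cohort.snp_info.to_csv(out / "snp_info.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)


def run_recover(cfg: Mapping, output_dir: str | Path | None = None, seed: int | None = None) -> pd.DataFrame:
    config = synth_config_from_mapping(cfg.get("simulation", cfg), seed=seed)
    report = end_to_end_truth_check(config)
    table = recovery_table(report)
    if output_dir is not None:
        out = Path(output_dir)
        _write_table(table, out / "recovery.tsv", dict(cfg, seed=config.seed))
        with open(out / "recovery.json", "w") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=2, default=float)
    return table
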