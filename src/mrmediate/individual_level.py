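"""One-sample MR with weighted allele scores and observational regression mediation.

Operates on an individual-level :class:`Cohort` (dosage matrix plus a
phenotype table). The one-sample MR estimator for a binary outcome is the
ratio of the reduced-form log-odds coefficient (logistic regression of the
outcome on the allele score) to the first-stage linear coefficient (exposure
on the score); for a continuous outcome it is two-stage least squares.
Observational mediation follows the classical product-of-coefficients /
difference constructions with nonparametric bootstrap uncertainty.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mr_estimators import MrEstimate, _normal_p
from .mvmr_mediation import (
    Effect,
    MediationEstimate,
    ProportionEstimate,
    product_indirect,
    proportion_mediated,
)

logger = logging.getLogger(__name__)


@dataclass
class Cohort:
    """Individual-level data: an n x m dosage matrix plus named phenotypes.

    ``genotypes`` holds effect-allele dosages in [0, 2] aligned to
    ``snp_ids``; ``snp_info`` (optional) carries per-SNP chromosome,
    position and allele labels for export to summary statistics.
    """

    genotypes: np.ndarray
    phenotypes: pd.DataFrame
    snp_ids: list[str]
    snp_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValueError("genotype columns do not match snp_ids")
        if self.genotypes.shape[0] != len(self.phenotypes):
            raise ValueError("genotype rows do not match phenotype rows")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if len(set(self.phenotypes.columns)) != len(self.phenotypes.columns):
            raise ValueError("phenotype column names must be unique")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def genotypes_float32(self) -> np.ndarray:
        """Float32 view of the dosage matrix, cached (used by large scans)."""
        if getattr(self, "_g32", None) is None:
            self._g32 = np.asarray(self.genotypes, dtype=np.float32)
        return self._g32

    def dosage(self, snp_id: str) -> np.ndarray:
        return np.asarray(self.genotypes[:, self._snp_index[snp_id]], dtype=float)

    def take(self, idx: np.ndarray) -> "Cohort":
        return Cohort(
            self.genotypes[idx],
            self.phenotypes.iloc[idx].reset_index(drop=True),
            list(self.snp_ids),
            self.snp_info,
        )


@dataclass
class ScoreDefinition:
    """Per-SNP weights (discovery-GWAS betas) for a weighted allele score."""

    snp_weights: dict[str, float]
    source_label: str = ""
    effect_alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.snp_weights.values()))):
            raise ValueError("score weights must be finite")
        if not any(w != 0 for w in self.snp_weights.values()):
            raise ValueError("score must have at least one nonzero weight")


def build_allele_score(cohort: Cohort, definition: ScoreDefinition) -> np.ndarray:
    """Weighted sum of effect-allele dosages, ``score_i = sum_k w_k g_ik``.

    When the definition carries effect-allele labels and the cohort has
    ``snp_info``, dosages are re-oriented (``g -> 2 - g``) for SNPs whose
    stored dosage allele differs from the weight's effect allele.
    """
    missing = [s for s in definition.snp_weights if s not in cohort._snp_index]
    if missing:
        raise KeyError(f"score SNPs absent from cohort: {missing}")
    cohort_alleles = {}
    if cohort.snp_info is not None and definition.effect_alleles:
        cohort_alleles = dict(
            zip(cohort.snp_info["SNP"], cohort.snp_info["EA"])
        )
    score = np.zeros(cohort.n)
    for sid, w in definition.snp_weights.items():
        g = cohort.dosage(sid)
        want = definition.effect_alleles.get(sid)
        if want is not None and cohort_alleles and cohort_alleles.get(sid) != want:
            g = 2.0 - g
        score += w * g
    return score


# ---------------------------------------------------------------------------
# fast logistic for bootstrap loops
# ---------------------------------------------------------------------------

def _fast_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10) -> np.ndarray:
    """Newton–Raphson logistic regression returning coefficients only.

    A minimal solver for small fixed designs, used inside bootstrap loops
    where per-fit overhead dominates; equivalence with statsmodels Logit is
    covered by tests.
    """
    beta = np.zeros(X.shape[1])
    p0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(p0 / (1 - p0))  # assumes X[:,0] is the constant
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _design(cohort: Cohort, cols: Sequence[str], extra: np.ndarray | None = None) -> np.ndarray:
    parts = [np.ones(cohort.n)]
    if extra is not None:
        parts.append(np.asarray(extra, dtype=float))
    for c in cols:
        parts.append(cohort.phenotypes[c].to_numpy(dtype=float))
    return np.column_stack(parts)


# ---------------------------------------------------------------------------
# one-sample MR
# ---------------------------------------------------------------------------

def one_sample_mr(
    cohort: Cohort,
    score: np.ndarray,
    exposure_col: str,
    outcome_col: str,
    covariates: Sequence[str] = (),
    first_stage_p_threshold: float = 1e-3,
) -> MrEstimate:
    """Allele-score instrumental-variable estimate of exposure on outcome.

    Binary outcome: ratio of the reduced-form logistic coefficient of the
    score to the first-stage linear coefficient, with a first-order delta
    SE (``se_reduced / |first_stage|``). Continuous outcome: two-stage least
    squares (outcome regressed on the first-stage fitted exposure). The
    first-stage association p-value is logged as an instrument sanity check.
    """
    score = np.asarray(score, dtype=float)
    if np.var(score) == 0:
        raise ValueError("allele score has zero variance")
    X = _design(cohort, covariates, extra=score)
    exposure = cohort.phenotypes[exposure_col].to_numpy(dtype=float)
    fs = sm.OLS(exposure, X).fit()
    fs_beta, fs_se, fs_p = fs.params[1], fs.bse[1], fs.pvalues[1]
    if fs_p > first_stage_p_threshold:
        logger.warning(
            "weak instrument: first-stage p = %.3g exceeds %.3g", fs_p, first_stage_p_threshold
        )
    y = cohort.phenotypes[outcome_col].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        rf = sm.Logit(y, X).fit(disp=0)
        beta = rf.params[1] / fs_beta
        se = rf.bse[1] / abs(fs_beta)
    else:
        fitted = fs.fittedvalues
        X2 = _design(cohort, covariates, extra=fitted)
        ss = sm.OLS(y, X2).fit()
        beta, se = ss.params[1], ss.bse[1]
    est = MrEstimate(beta=float(beta), se=float(se), method="one_sample_ratio", n_snps=1)
    est.extra.update({"first_stage_beta": float(fs_beta), "first_stage_p": float(fs_p)})
    return est


def multivariable_one_sample_mr(
    cohort: Cohort,
    scores: Mapping[str, np.ndarray],
    exposure_cols: Sequence[str],
    outcome_col: str,
    covariates: Sequence[str] = (),
) -> dict[str, Effect]:
    """Joint one-sample MR with one allele score per exposure.

    Solves the linear system relating reduced-form coefficients (outcome on
    all scores) to first-stage coefficients (each exposure on all scores):
    ``c = B theta`` where ``B[s, j]`` is the coefficient of score ``s`` in
    the first-stage regression of exposure ``j``, giving the direct effect
    of each exposure conditional on the others. SEs propagate the
    reduced-form coefficient covariance through the inverse first stage
    (first-stage estimation noise is neglected; with strong scores it is
    second order).
    """
    names = list(scores)
    S = np.column_stack([np.asarray(scores[n], dtype=float) for n in names])
    X = _design(cohort, covariates, extra=S)
    q = len(names)
    B = np.zeros((q, len(exposure_cols)))  # score x exposure first-stage betas
    for j, col in enumerate(exposure_cols):
        fs = sm.OLS(cohort.phenotypes[col].to_numpy(dtype=float), X).fit()
        B[:, j] = fs.params[1 : 1 + q]
    y = cohort.phenotypes[outcome_col].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    rf = sm.Logit(y, X).fit(disp=0) if binary else sm.OLS(y, X).fit()
    c = rf.params[1 : 1 + q]
    cov_c = rf.cov_params()[1 : 1 + q, 1 : 1 + q]
    Binv = np.linalg.inv(B)
    theta = Binv @ c
    cov_theta = Binv @ cov_c @ Binv.T
    ses = np.sqrt(np.diag(cov_theta))
    return {col: Effect(float(t), float(s)) for col, t, s in zip(exposure_cols, theta, ses)}


# ---------------------------------------------------------------------------
# phenotype derivations
# ---------------------------------------------------------------------------

def adjust_sbp_for_medication(sbp, on_medication):
    """Add 10 mm Hg to measured systolic blood pressure for treated individuals."""
    sbp = np.asarray(sbp, dtype=float)
    med = np.asarray(on_medication, dtype=bool)
    if np.any(sbp <= 0):
        raise ValueError("systolic blood pressure must be positive")
    out = sbp + 10.0 * med
    return float(out) if out.ndim == 0 else out


#: default qualification -> years-of-schooling table (ISCED-style mapping
#: of the UK qualification categories; configurable).
DEFAULT_ISCED_YEARS: dict[str, int] = {
    "college or university degree": 20,
    "nvq or hnd or hnc or equivalent": 19,
    "other professional qualifications": 15,
    "a levels/as levels or equivalent": 13,
    "o levels/gcses or equivalent": 10,
    "cses or equivalent": 10,
    "none of the above": 7,
}


def map_qualifications_to_years(
    qualification: str, mapping: Mapping[str, int] | None = None
) -> int:
    """Convert a highest-qualification category to years of schooling."""
    table = DEFAULT_ISCED_YEARS if mapping is None else mapping
    key = qualification.strip().lower()
    if key not in table:
        raise KeyError(f"unknown qualification category {qualification!r}")
    return int(table[key])


# ---------------------------------------------------------------------------
# observational regression
# ---------------------------------------------------------------------------

def observational_total(
    cohort: Cohort,
    exposure_col: str,
    outcome_col: str,
    confounders: Sequence[str] = (),
) -> MrEstimate:
    """Confounder-adjusted logistic regression of outcome on exposure.

    The exposure is expected on a per-SD scale; the coefficient is reported
    as a log odds ratio per SD (exponentiate for the OR).
    """
    y = cohort.phenotypes[outcome_col].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("observational_total requires a binary outcome column")
    X = _design(cohort, confounders, extra=cohort.phenotypes[exposure_col].to_numpy(dtype=float))
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # perfect separation and friends
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible separation)")
    return MrEstimate(
        beta=float(res.params[1]), se=float(res.bse[1]),
        method="observational_logistic", n_snps=1,
    )


def _mediation_point(
    X_conf: np.ndarray,
    exposure: np.ndarray,
    mediators: np.ndarray,
    y: np.ndarray,
    single: bool,
    linear_probability: bool,
) -> tuple[float, float, float, float]:
    """(total, direct-or-b, a, proportion) on one dataset/resample."""
    n = len(y)
    Xt = np.column_stack([X_conf[:, :1], exposure[:, None], X_conf[:, 1:]])
    if linear_probability:
        total = np.linalg.lstsq(Xt, y, rcond=None)[0][1]
    else:
        total = _fast_logit(Xt, y)[1]
    Xm = np.column_stack(
        [X_conf[:, :1], mediators, exposure[:, None], X_conf[:, 1:]]
    )
    if single:
        a = np.linalg.lstsq(Xt, mediators[:, 0], rcond=None)[0][1]
        if linear_probability:
            b = np.linalg.lstsq(Xm, y, rcond=None)[0][1]
        else:
            b = _fast_logit(Xm, y)[1]
        indirect = a * b
        return total, b, a, indirect / total
    if linear_probability:
        direct = np.linalg.lstsq(Xm, y, rcond=None)[0][1 + mediators.shape[1]]
    else:
        direct = _fast_logit(Xm, y)[1 + mediators.shape[1]]
    return total, direct, np.nan, (total - direct) / total


def observational_mediation(
    cohort: Cohort,
    exposure_col: str,
    mediator_cols: Sequence[str],
    outcome_col: str,
    confounders: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int | None = None,
    scale: str = "logit",
    se_method: str = "bootstrap",
) -> MediationEstimate:
    """Observational mediation with bootstrap uncertainty.

    One mediator: product of coefficients — ``a`` from linear regression of
    the mediator on exposure (plus confounders), ``b`` from logistic
    regression of the outcome on mediator + exposure + confounders; indirect
    = ``a*b`` on the log-odds scale; ``P`` = indirect/total. Several
    mediators: difference method ``P = (T - D)/T`` with D from the
    outcome model including all mediators. ``scale='risk_difference'``
    replaces every logistic fit with a linear probability model. SEs and
    percentile CIs come from ``n_boot`` nonparametric resamples of
    individuals (``se_method='delta'`` gives the fast Sobel/delta
    alternative without resampling).
    """
    if se_method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
    if scale not in ("logit", "risk_difference"):
        raise ValueError("scale must be 'logit' or 'risk_difference'")
    linear_probability = scale == "risk_difference"
    single = len(mediator_cols) == 1

    y = cohort.phenotypes[outcome_col].to_numpy(dtype=float)
    if not linear_probability and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic mediation requires a binary outcome column")
    exposure = cohort.phenotypes[exposure_col].to_numpy(dtype=float)
    mediators = cohort.phenotypes[list(mediator_cols)].to_numpy(dtype=float)
    X_conf = _design(cohort, confounders)

    total, second, a, point = _mediation_point(
        X_conf, exposure, mediators, y, single, linear_probability
    )

    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = cohort.n
        props = np.empty(n_boot)
        totals = np.empty(n_boot)
        indirects = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            t_i, s_i, a_i, p_i = _mediation_point(
                X_conf[idx], exposure[idx], mediators[idx], y[idx], single, linear_probability
            )
            props[i] = p_i
            totals[i] = t_i
            indirects[i] = (a_i * s_i) if single else (t_i - s_i)
        prop = ProportionEstimate(
            point,
            float(np.std(props, ddof=1)),
            float(np.percentile(props, 2.5)),
            float(np.percentile(props, 97.5)),
        )
        total_eff = Effect(float(total), float(np.std(totals, ddof=1)))
        indirect_eff = Effect(
            float(a * second) if single else float(total - second),
            float(np.std(indirects, ddof=1)),
        )
        direct_eff = None if single else Effect(float(second), float(np.std(totals - indirects, ddof=1)))
    else:
        # delta path: refit with statsmodels for coefficient SEs
        Xt = np.column_stack([X_conf[:, :1], exposure[:, None], X_conf[:, 1:]])
        tot_fit = sm.OLS(y, Xt).fit() if linear_probability else sm.Logit(y, Xt).fit(disp=0)
        total_eff = Effect(float(tot_fit.params[1]), float(tot_fit.bse[1]))
        Xm = np.column_stack([X_conf[:, :1], mediators, exposure[:, None], X_conf[:, 1:]])
        out_fit = sm.OLS(y, Xm).fit() if linear_probability else sm.Logit(y, Xm).fit(disp=0)
        if single:
            a_fit = sm.OLS(mediators[:, 0], Xt).fit()
            a_eff = Effect(float(a_fit.params[1]), float(a_fit.bse[1]))
            b_eff = Effect(float(out_fit.params[1]), float(out_fit.bse[1]))
            indirect_eff = product_indirect(a_eff, b_eff)
            direct_eff = None
        else:
            j = 1 + mediators.shape[1]
            direct_eff = Effect(float(out_fit.params[j]), float(out_fit.bse[j]))
            indirect_eff = Effect(
                total_eff.beta - direct_eff.beta,
                float(np.sqrt(total_eff.se**2 + direct_eff.se**2)),
            )
        prop = proportion_mediated(indirect_eff, total_eff)

    components = {}
    if single:
        components = {"a": Effect(float(a), np.nan), "b": Effect(float(second), np.nan)} \
            if se_method == "bootstrap" else {"a": a_eff, "b": b_eff}
    return MediationEstimate(
        total=total_eff,
        indirect=indirect_eff,
        proportion=prop,
        direct=direct_eff,
        method="product_observational" if single else "difference_combined",
        components=components,
    )
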