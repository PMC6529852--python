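"""Multivariable MR and mediation: product-of-coefficients and difference methods.

Two-step MR mediation decomposes the total effect T of an exposure (here,
years of education per SD) on a binary outcome into a path through a
mediator and a direct remainder, all on the log-odds scale:

* ``a`` — MR effect of exposure on mediator (IVW over the exposure panel),
* ``b`` — effect of mediator on outcome conditional on exposure, the
  mediator coefficient of a multivariable MR over the union of both panels,
* indirect effect ``a*b`` with a Sobel (delta-method) SE,
* proportion mediated ``P = a*b / T``.

For several mediators jointly the difference method is used instead:
``P = (T - D)/T`` with D the exposure's direct coefficient from a
multivariable MR including all mediators.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .mr_estimators import Z95, MrEstimate, _normal_p, ivw_fixed
from .summary_core import HarmonisedSet, SummarySet, _align_orientation, harmonise


class Effect(NamedTuple):
    """A point estimate with its standard error."""

    beta: float
    se: float


@dataclass
class MvmrRow:
    snp_id: str
    bx: np.ndarray       # one beta per exposure
    sx: np.ndarray
    by: float
    sy: float


@dataclass
class MultiHarmonisedSet:
    """Per-SNP betas for several exposures plus the outcome, allele-aligned.

    The first exposure is the primary one (education); alignment is to the
    first exposure panel's effect alleles.
    """

    exposure_names: list[str]
    rows: list[MvmrRow] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        bx = np.array([r.bx for r in self.rows])
        sx = np.array([r.sx for r in self.rows])
        by = np.array([r.by for r in self.rows])
        sy = np.array([r.sy for r in self.rows])
        return bx, sx, by, sy


@dataclass
class MvmrEstimate:
    """Coefficients of a multivariable MR fit, one per exposure."""

    coefficients: dict[str, tuple[float, float, float]]  # name -> (beta, se, p)
    n_snps: int
    diagnostics: dict[str, float] = field(default_factory=dict)

    def effect(self, exposure: str) -> Effect:
        beta, se, _ = self.coefficients[exposure]
        return Effect(beta, se)


@dataclass
class ProportionEstimate:
    point: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class MediationEstimate:
    """Total/direct/indirect decomposition with the proportion mediated."""

    total: Effect
    indirect: Effect
    proportion: ProportionEstimate
    method: str
    direct: Effect | None = None
    components: dict[str, Effect] = field(default_factory=dict)
    n_snps: int = 0


# ---------------------------------------------------------------------------
# multivariable harmonisation and fit
# ---------------------------------------------------------------------------

def harmonise_multi(
    exposures: Sequence[SummarySet],
    outcome: SummarySet,
    snp_ids: Sequence[str] | None = None,
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_window: float = 0.08,
) -> MultiHarmonisedSet:
    """Align several exposure panels and one outcome panel per SNP.

    SNPs are kept only when an association estimate exists in *every*
    exposure set and the outcome set (missing-estimate SNPs are dropped and
    counted); each non-reference set is oriented to the first exposure's
    effect allele with the same allele rules as pairwise harmonisation.
    """
    ref = exposures[0]
    candidates = list(snp_ids) if snp_ids is not None else list(ref.records)
    names = [s.trait_name for s in exposures]
    out = MultiHarmonisedSet(exposure_names=names)
    for sid in candidates:
        if sid not in ref.records:
            out.dropped.append((sid, f"missing_in_{ref.trait_name}"))
            continue
        r = ref.records[sid]
        missing = [s.trait_name for s in exposures[1:] if sid not in s.records]
        if sid not in outcome.records:
            missing.append(outcome.trait_name)
        if missing:
            out.dropped.append((sid, "missing_in_" + ",".join(missing)))
            continue
        bx = [r.beta]
        sx = [r.se]
        ok = True
        for sset in exposures[1:]:
            sign, reason = _align_orientation(
                r, sset.records[sid], palindrome_policy, eaf_ambiguity_window
            )
            if sign == 0:
                out.dropped.append((sid, reason))
                ok = False
                break
            bx.append(sign * sset.records[sid].beta)
            sx.append(sset.records[sid].se)
        if not ok:
            continue
        o = outcome.records[sid]
        sign, reason = _align_orientation(r, o, palindrome_policy, eaf_ambiguity_window)
        if sign == 0:
            out.dropped.append((sid, reason))
            continue
        out.rows.append(
            MvmrRow(sid, np.array(bx), np.array(sx), sign * o.beta, o.se)
        )
        out.provenance[sid] = names
    return out


def mvmr_fit(m: MultiHarmonisedSet, subtract_exposure_noise: bool = False) -> MvmrEstimate:
    """Weighted least squares of outcome betas on the exposure-beta matrix.

    No intercept; weights ``1/sy^2``; SEs from the weighted normal equations
    with a multiplicative overdispersion scale ``max(1, sqrt(RSS_w/(k-p)))``.
    Exposure columns that are exactly zero carry no information and are
    excluded from the solve (their coefficient is reported as 0 with an
    infinite SE); rank deficiency among the remaining columns is an error
    naming the collinear exposures.

    ``subtract_exposure_noise`` applies an errors-in-variables correction:
    the exposure betas are GWAS estimates whose known sampling variances
    ``sx^2`` inflate the weighted Gram matrix and attenuate coefficients
    (regression-dilution within MVMR). The correction subtracts
    ``sum_j w_j diag(sx_j^2)`` from ``X'WX`` before solving, which is
    consistent as the panels grow. The default keeps the uncorrected
    estimator, the conventional regression form.
    """
    bx, sx, by, sy = m.matrices()
    k, p = bx.shape
    if k <= p:
        raise ValueError(f"MVMR needs more SNPs ({k}) than exposures ({p})")
    nonzero = ~np.all(bx == 0, axis=0)
    X = bx[:, nonzero]
    w = 1.0 / sy**2
    sw = np.sqrt(w)
    if np.linalg.matrix_rank(sw[:, None] * X) < X.shape[1]:
        kept_names = [n for n, nz in zip(m.exposure_names, nonzero) if nz]
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (kept_names[i], kept_names[j])
            for i in range(X.shape[1]) for j in range(i + 1, X.shape[1])
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"exposure beta matrix is rank deficient; collinear: {pairs}")
    xtwx = X.T @ (w[:, None] * X)
    if subtract_exposure_noise:
        xtwx = xtwx - np.diag((w[:, None] * sx[:, nonzero] ** 2).sum(axis=0))
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (k - X.shape[1])))
    cov = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov)) * scale

    coefficients: dict[str, tuple[float, float, float]] = {}
    j = 0
    diagnostics: dict[str, float] = {}
    for i, name in enumerate(m.exposure_names):
        if nonzero[i]:
            beta, se = float(coef[j]), float(ses[j])
            coefficients[name] = (beta, se, _normal_p(beta, se))
            j += 1
        else:
            coefficients[name] = (0.0, float("inf"), 1.0)
        # mean instrument-strength chi-square for this exposure (logged only)
        with np.errstate(divide="ignore", invalid="ignore"):
            diagnostics[name] = float(np.mean((bx[:, i] / sx[:, i]) ** 2))
    return MvmrEstimate(coefficients=coefficients, n_snps=k, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# mediation algebra
# ---------------------------------------------------------------------------

def product_indirect(a: Effect | MrEstimate, b: Effect | tuple[float, float]) -> Effect:
    """Indirect effect ``a*b`` with the Sobel (no-covariance) delta SE."""
    a_beta, a_se = (a.beta, a.se)
    b_beta, b_se = b[0], b[1]
    beta = a_beta * b_beta
    se = float(np.sqrt(a_beta**2 * b_se**2 + b_beta**2 * a_se**2))
    return Effect(float(beta), se)


def proportion_mediated(
    indirect: Effect | tuple[float, float],
    total: Effect | tuple[float, float],
    se_method: str = "delta",
    bootstrap_samples: np.ndarray | None = None,
) -> ProportionEstimate:
    """Proportion mediated ``P = indirect/total`` with a 95% CI.

    The delta SE treats the indirect and total effects as independent:
    ``var(P) = (se_i/T)^2 + (I * se_T / T^2)^2`` (equal to the classical
    ``|P| sqrt((se_i/I)^2 + (se_T/T)^2)`` for nonzero I, and well defined at
    I = 0). Alternatively ``se_method='bootstrap_samples'`` takes the SD and
    percentile CI of supplied resampled proportions. CIs are never truncated
    to [0, 1].
    """
    i_beta, i_se = indirect[0], indirect[1]
    t_beta, t_se = total[0], total[1]
    if t_beta == 0:
        raise ZeroDivisionError("proportion undefined under null total effect")
    point = i_beta / t_beta
    if se_method == "delta":
        var = (i_se / t_beta) ** 2 + (i_beta * t_se / t_beta**2) ** 2
        se = float(np.sqrt(var))
        return ProportionEstimate(point, se, point - Z95 * se, point + Z95 * se)
    if se_method == "bootstrap_samples":
        if bootstrap_samples is None:
            raise ValueError("bootstrap_samples required")
        samples = np.asarray(bootstrap_samples, dtype=float)
        se = float(np.std(samples, ddof=1))
        lo, hi = np.percentile(samples, [2.5, 97.5])
        return ProportionEstimate(point, se, float(lo), float(hi))
    raise ValueError(f"unknown se_method {se_method!r}")


def two_step_mediation(
    education: SummarySet,
    mediator: SummarySet,
    outcome: SummarySet,
    edu_instruments: Sequence[str] | None = None,
    mediator_instruments: Sequence[str] | None = None,
    harmonise_options: dict | None = None,
) -> MediationEstimate:
    """Two-step MR mediation by the product of coefficients.

    ``education`` and ``mediator`` are association panels for the two traits
    covering (at least) the union of the two instrument lists; ``outcome``
    covers the same SNPs. Steps: ``a`` = IVW of education instruments on the
    mediator; ``T`` = IVW of education instruments on the outcome; ``b`` =
    mediator coefficient of the multivariable MR (education, mediator) over
    the instrument union; indirect = ``a*b``; ``P`` = indirect / T with a
    delta-method SE.
    """
    hopts = harmonise_options or {}
    edu_ids = list(edu_instruments) if edu_instruments is not None else education.snp_ids
    med_ids = (
        list(mediator_instruments) if mediator_instruments is not None else mediator.snp_ids
    )
    edu_panel = education.subset(edu_ids)
    a = ivw_fixed(harmonise(edu_panel, mediator, **hopts))
    t = ivw_fixed(harmonise(edu_panel, outcome, **hopts))
    union = list(dict.fromkeys([*edu_ids, *med_ids]))
    multi = harmonise_multi([education, mediator], outcome, snp_ids=union, **hopts)
    fit = mvmr_fit(multi)
    b = fit.effect(mediator.trait_name)
    indirect = product_indirect(Effect(a.beta, a.se), b)
    prop = proportion_mediated(indirect, Effect(t.beta, t.se))
    return MediationEstimate(
        total=Effect(t.beta, t.se),
        indirect=indirect,
        proportion=prop,
        method="product_two_step",
        components={"a": Effect(a.beta, a.se), "b": b},
        n_snps=len(multi),
    )


def combined_difference(total: MrEstimate | Effect, direct: MvmrEstimate, exposure: str | None = None) -> MediationEstimate:
    """Difference-method mediation for all mediators jointly.

    ``P = (T - D)/T`` where D is the primary exposure's coefficient from a
    multivariable MR including every mediator. The delta SE treats T and D
    as independent: ``var(P) = (se_D/T)^2 + (D se_T / T^2)^2``.
    """
    t_beta, t_se = total.beta, total.se
    if t_beta == 0:
        raise ZeroDivisionError("proportion undefined under null total effect")
    name = exposure or next(iter(direct.coefficients))
    d_beta, d_se = direct.effect(name)
    point = (t_beta - d_beta) / t_beta
    var = (d_se / t_beta) ** 2 + (d_beta * t_se / t_beta**2) ** 2
    se = float(np.sqrt(var))
    prop = ProportionEstimate(point, se, point - Z95 * se, point + Z95 * se)
    indirect = Effect(t_beta - d_beta, float(np.sqrt(t_se**2 + d_se**2)))
    return MediationEstimate(
        total=Effect(t_beta, t_se),
        direct=Effect(d_beta, d_se),
        indirect=indirect,
        proportion=prop,
        method="difference_combined",
        n_snps=direct.n_snps,
    )


def serialise_mediation(results, exposure: str, outcome: str):
    """Flat mediation table matching the documented column contract."""
    import pandas as pd

    rows = []
    for mediator, est in results:
        rows.append({
            "exposure": exposure, "mediator": mediator, "outcome": outcome,
            "method": est.method,
            "total_beta": est.total.beta, "total_se": est.total.se,
            "direct_beta": est.direct.beta if est.direct else np.nan,
            "direct_se": est.direct.se if est.direct else np.nan,
            "indirect_beta": est.indirect.beta, "indirect_se": est.indirect.se,
            "prop": est.proportion.point, "prop_se": est.proportion.se,
            "prop_ci_low": est.proportion.ci_low, "prop_ci_high": est.proportion.ci_high,
            "n_snps": est.n_snps,
        })
    return pd.DataFrame(rows)
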