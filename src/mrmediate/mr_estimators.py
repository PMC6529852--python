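"""Two-sample Mendelian randomisation estimators.

All estimators operate on a :class:`~mrmediate.summary_core.HarmonisedSet`
of per-SNP exposure/outcome associations and return an :class:`MrEstimate`
whose ``beta`` is the causal effect of one SD (or one unit) of exposure on
the outcome scale — log odds for binary outcomes. Exponentiation to an odds
ratio happens only at report rendering.

Estimators:

* :func:`wald_ratio` — single-SNP ratio estimate with first- or
  second-order delta-method SE,
* :func:`ivw_fixed` — fixed-effect inverse-variance weighted pooling of the
  per-SNP ratios (with first-order weights this is exactly weighted least
  squares of the outcome betas on the exposure betas through the origin),
* :func:`mr_egger` — weighted regression with an intercept; the intercept
  is a test for directional pleiotropy and the slope a pleiotropy-robust
  effect estimate,
* :func:`weighted_median` — the inverse-variance weighted median of the
  per-SNP ratios, consistent when at least half the weight comes from valid
  instruments; SE by parametric bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_core import HarmonisedSet, SummarySet, harmonise

#: normal 97.5% quantile used for all Wald CIs
Z95 = 1.959964


@dataclass
class MrEstimate:
    """A causal effect estimate with its Wald interval and method tag."""

    beta: float
    se: float
    method: str
    n_snps: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    pvalue: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se
        if not self.pvalue:
            self.pvalue = _normal_p(self.beta, self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def _normal_p(beta: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(beta) / se))


def _ratio_se(bx, sx, by, sy, se_order: str) -> np.ndarray:
    if se_order == "first":
        return np.abs(sy / bx)
    if se_order == "second":
        return np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")


def wald_ratio(bx: float, sx: float, by: float, sy: float, se_order: str = "first") -> MrEstimate:
    """Single-SNP ratio estimate ``by/bx`` with a delta-method SE.

    First-order SE is ``sy/|bx|``; second-order additionally propagates the
    exposure-beta uncertainty: ``sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4)``.
    """
    if bx == 0:
        raise ZeroDivisionError("weak/zero instrument: ratio undefined for bx = 0")
    beta = by / bx
    se = float(_ratio_se(np.float64(bx), np.float64(sx), np.float64(by), np.float64(sy), se_order))
    return MrEstimate(beta=beta, se=se, method="wald_ratio", n_snps=1)


def ivw_fixed(h: HarmonisedSet, se_order: str = "first") -> MrEstimate:
    """Fixed-effect inverse-variance weighted pooling of per-SNP ratios.

    Each SNP contributes a Wald ratio ``r_j = by_j/bx_j`` with weight
    ``w_j = 1/se(r_j)^2``; the pooled estimate is ``sum(w r)/sum(w)`` with
    SE ``sqrt(1/sum(w))``. With first-order ratio SEs this is identical to
    weighted least squares of ``by`` on ``bx`` through the origin with
    weights ``1/sy^2``.
    """
    bx, sx, by, sy = h.arrays()
    keep = bx != 0
    if not keep.any():
        raise ValueError("IVW requires at least one SNP with nonzero exposure beta")
    bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    ratios = by / bx
    w = 1.0 / _ratio_se(bx, sx, by, sy, se_order) ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return MrEstimate(beta=beta, se=se, method="ivw_fixed", n_snps=int(keep.sum()))


def mr_egger(h: HarmonisedSet, orient: bool = True, overdispersion: str = "multiplicative") -> MrEstimate:
    """Egger regression: weighted least squares of by on bx with an intercept.

    When ``orient`` each SNP's signs are flipped so exposure betas are
    non-negative (the estimator is defined up to this orientation). Weights
    are ``1/sy^2``. The slope estimates the causal effect; the intercept
    estimates the average directional pleiotropy, tested two-sided against
    a t distribution with k-2 df. SEs carry a multiplicative overdispersion
    factor ``max(1, sqrt(RSS_w/(k-2)))`` unless ``overdispersion='fixed'``.
    """
    bx, sx, by, sy = h.arrays()
    k = len(bx)
    if k < 3:
        raise ValueError("Egger requires >=3 instruments")
    if orient:
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (k - 2))) if overdispersion == "multiplicative" else 1.0
    cov_unit = np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov_unit)) * scale
    intercept, slope = coef
    se_int, se_slope = ses
    intercept_p = float(2 * stats.t.sf(abs(intercept) / se_int, df=k - 2))
    return MrEstimate(
        beta=float(slope),
        se=float(se_slope),
        method="egger",
        n_snps=k,
        extra={
            "egger_intercept": float(intercept),
            "egger_intercept_se": float(se_int),
            "egger_intercept_p": intercept_p,
            "overdispersion_scale": float(scale),
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative-weight midpoints vs 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    q = np.cumsum(w) - w / 2
    return float(np.interp(0.5, q, r))


def weighted_median(h: HarmonisedSet, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Inverse-variance weighted median of per-SNP ratios.

    The point estimate interpolates the sorted ratios against their
    cumulative-weight midpoints at probability 0.5. The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples drawing
    ``bx_j ~ N(bx_j, sx_j)`` and ``by_j ~ N(by_j, sy_j)``; ``seed`` is
    mandatory so runs are reproducible.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    bx, sx, by, sy = h.arrays()
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median requires >=3 instruments")
    ratios = by / bx
    weights = (bx / sy) ** 2  # 1 / (sy/|bx|)^2, first-order ratio weights
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = bys[i] / bxs[i]
            w = (bxs[i] / sy) ** 2
        ok = np.isfinite(r) & np.isfinite(w) & (w > 0)
        boot[i] = _weighted_median_point(r[ok], w[ok])
    se = float(np.std(boot, ddof=1))
    return MrEstimate(beta=point, se=se, method="weighted_median", n_snps=k)


_DISPATCH = {
    "ivw_fixed": ivw_fixed,
    "egger": mr_egger,
    "weighted_median": weighted_median,
}


def estimate_total_effect(
    exposure: SummarySet,
    outcome: SummarySet,
    method: str = "ivw_fixed",
    harmonise_options: dict | None = None,
    **method_options,
) -> MrEstimate:
    """Harmonise two panels and dispatch to the requested estimator.

    A single-SNP panel with ``method='ivw_fixed'`` degenerates to the Wald
    ratio of that SNP.
    """
    h = harmonise(exposure, outcome, **(harmonise_options or {}))
    if method == "wald_ratio":
        if len(h) != 1:
            raise ValueError("wald_ratio requires exactly one harmonised SNP")
        r = h.rows[0]
        return wald_ratio(r.bx, r.sx, r.by, r.sy, **method_options)
    if method not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}")
    est = _DISPATCH[method](h, **method_options)
    est.extra.setdefault("n_dropped", len(h.dropped))
    return est


def serialise_estimates(estimates, exposure: str, outcome: str):
    """Flat result table: one row per estimate, OR columns exponentiated."""
    import json

    import pandas as pd

    rows = []
    for est in estimates:
        rows.append({
            "exposure": exposure, "outcome": outcome, "method": est.method,
            "n_snps": est.n_snps, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
            "or": np.exp(est.beta), "or_low": np.exp(est.ci_low),
            "or_high": np.exp(est.ci_high), "extra_json": json.dumps(est.extra),
        })
    return pd.DataFrame(rows)
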