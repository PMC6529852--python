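"""Ground-truth cohort simulator and derived GWAS summary statistics.

The generator emulates the causal structure the analysis assumes:

    instruments -> education -> {BMI, SBP, smoking} -> binary CVD outcome

with an unobserved confounder U loading on the exposure, every mediator and
the outcome, and classical measurement error on the observed mediators.
Education and the latent mediators are unit-variance; the outcome is
Bernoulli with a logistic link so all generating effects are natively
log odds. Every estimand (total, per-mediator indirect, proportions
mediated) is known in closed form from the configuration, enabling
parameter-recovery tests of the full two-sample, one-sample and
observational pipelines.

Default effect sizes are anchored to the magnitudes reported for the
education -> cardiovascular-disease system: total effect ln(0.63) per SD of
education, per-SD education effects on BMI/SBP/smoking of -0.22/-0.15/-0.32,
and mediator -> outcome log-odds effects solved so the per-mediator
proportions mediated are 0.18, 0.21 and 0.34.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .individual_level import Cohort
from .summary_core import SnpAssociation, SummarySet

MEDIATORS = ("bmi", "sbp", "smoking")

#: anchor quantities the defaults are built from
_TOTAL_LOG_OR = math.log(0.63)
_TARGET_PROPORTIONS = {"bmi": 0.18, "sbp": 0.21, "smoking": 0.34}
_THETA = {"bmi": -0.22, "sbp": -0.15, "smoking": -0.32}


def _default_beta_mediator() -> dict[str, float]:
    # beta_i = P_i * T / theta_i so that theta_i * beta_i = P_i * T
    return {
        m: _TARGET_PROPORTIONS[m] * _TOTAL_LOG_OR / _THETA[m] for m in MEDIATORS
    }


def _default_beta_direct() -> float:
    return _TOTAL_LOG_OR * (1.0 - sum(_TARGET_PROPORTIONS.values()))


@dataclass
class SynthConfig:
    """Generating parameters for one simulated study.

    ``instrument_r2`` is the variance in education explained by its
    instrument panel (0.12, the order reported for the large education
    GWAS); ``mediator_instrument_r2`` the same for each mediator panel.
    ``theta`` are education -> mediator effects in SD units;
    ``beta_mediator`` mediator -> outcome log-odds effects; ``beta_direct``
    the direct education -> outcome log-odds effect. ``gamma_u``,
    ``delta_u``, ``phi_u`` are confounder loadings on exposure, mediators
    and outcome. ``reliability`` gives each observed mediator's classical
    measurement reliability (share of observed variance that is signal).
    """

    n: int = 100_000
    m_instruments: int = 100
    maf_range: tuple[float, float] = (0.05, 0.45)
    instrument_r2: float = 0.12
    mediator_instrument_r2: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.06, "sbp": 0.05, "smoking": 0.04}
    )
    theta: dict[str, float] = field(default_factory=lambda: dict(_THETA))
    beta_mediator: dict[str, float] = field(default_factory=_default_beta_mediator)
    beta_direct: float = field(default_factory=_default_beta_direct)
    gamma_u: float = 0.3
    delta_u: dict[str, float] = field(
        default_factory=lambda: {m: 0.15 for m in MEDIATORS}
    )
    phi_u: float = 0.4
    reliability: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.95, "sbp": 0.6, "smoking": 0.6}
    )
    outcome_prevalence: float = 0.05
    pleiotropy_fraction: float = 0.0
    pleiotropy_effect: float = 0.0
    seed: int = 0
    #: seed for the genetic architecture (MAFs, per-SNP effects, allele
    #: labels). Defaults to ``seed``; set it explicitly to draw several
    #: independent cohorts from the *same* population, e.g. the separate
    #: exposure- and outcome-side samples of a two-sample design.
    architecture_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 < self.instrument_r2 < 1):
            raise ValueError("instrument_r2 must be in (0, 1)")
        for m in MEDIATORS:
            if not (0 < self.reliability[m] <= 1):
                raise ValueError(f"reliability[{m}] must be in (0, 1]")
        if not (0 < self.outcome_prevalence < 1):
            raise ValueError("outcome_prevalence must be in (0, 1)")


@dataclass
class SimulationTruth:
    """Closed-form estimands implied by a :class:`SynthConfig`.

    On the generator's (log-odds-linear) scale the decomposition is exact:
    ``true_total = true_direct + sum(true_indirect)``.
    """

    true_total: float
    true_direct: float
    true_indirect: dict[str, float]
    true_proportion: dict[str, float]
    true_proportion_combined: float

    @classmethod
    def from_config(cls, config: SynthConfig) -> "SimulationTruth":
        indirect = {m: config.theta[m] * config.beta_mediator[m] for m in MEDIATORS}
        total = config.beta_direct + sum(indirect.values())
        props = {m: indirect[m] / total for m in MEDIATORS}
        return cls(
            true_total=total,
            true_direct=config.beta_direct,
            true_indirect=indirect,
            true_proportion=props,
            true_proportion_combined=sum(props.values()),
        )


PANELS = ("education",) + MEDIATORS


def panel_slices(config: SynthConfig) -> dict[str, slice]:
    """Column ranges of each trait's instrument panel in the dosage matrix."""
    m = config.m_instruments
    return {t: slice(i * m, (i + 1) * m) for i, t in enumerate(PANELS)}


def panel_snp_ids(config: SynthConfig, trait: str) -> list[str]:
    m = config.m_instruments
    return [f"{trait}_{k:04d}" for k in range(m)]


def _scaled_effects(rng, mafs: np.ndarray, r2: float) -> np.ndarray:
    """Per-SNP additive effects with random signs scaled to explain r2."""
    raw = rng.normal(0.0, 1.0, size=mafs.size)
    var = np.sum(raw**2 * 2 * mafs * (1 - mafs))
    return raw * np.sqrt(r2 / var)


def simulate_cohort(config: SynthConfig) -> tuple[Cohort, SimulationTruth]:
    """Draw one cohort and report its closed-form ground truth.

    Dosages are Binomial(2, maf) and independent across SNPs; education,
    latent mediators and the confounder are unit-variance Gaussians linked
    by the configured structural coefficients; observed mediators add
    classical measurement noise ``Var = 1/reliability - 1``; the outcome is
    Bernoulli(logistic(...)) driven by the *latent* mediators. Residual
    variances are solved so every trait has unit variance; an infeasible
    variance budget (negative residual) is an error.
    """
    m = config.m_instruments
    n = config.n
    slices = panel_slices(config)
    total_snps = m * len(PANELS)

    # population-level architecture: shared across cohorts drawn with the
    # same architecture seed
    arch_seed = config.architecture_seed if config.architecture_seed is not None else config.seed
    arch = np.random.default_rng(arch_seed)
    mafs = arch.uniform(*config.maf_range, size=total_snps).astype(np.float32)
    alpha = _scaled_effects(arch, mafs[slices["education"]].astype(float), config.instrument_r2)
    a_meds = {
        med: _scaled_effects(
            arch, mafs[slices[med]].astype(float), config.mediator_instrument_r2[med]
        )
        for med in MEDIATORS
    }
    bases = np.array(list("ACGT"))
    ea = bases[arch.integers(0, 4, size=total_snps)]
    oa = np.array([bases[(list(bases).index(a) + 1 + arch.integers(0, 3)) % 4] for a in ea])
    pleio_idx = None
    if config.pleiotropy_fraction > 0 and config.pleiotropy_effect != 0:
        n_pleio = int(round(config.pleiotropy_fraction * m))
        pleio_idx = arch.choice(m, size=n_pleio, replace=False)

    rng = np.random.default_rng(config.seed)
    # two Bernoulli draws per haplotype; float32 uniforms for speed
    G = (rng.random((n, total_snps), dtype=np.float32) < mafs).astype(np.int8)
    G += (rng.random((n, total_snps), dtype=np.float32) < mafs).astype(np.int8)
    G32 = G.astype(np.float32)

    def panel_contribution(sl: slice, effects: np.ndarray) -> np.ndarray:
        eff32 = effects.astype(np.float32)
        return G32[:, sl] @ eff32 - float(np.dot(2 * mafs[sl], eff32))

    U = rng.standard_normal(n)

    # education
    var_eps_e = 1.0 - config.instrument_r2 - config.gamma_u**2
    if var_eps_e <= 0:
        raise ValueError("infeasible variance budget for education")
    E = panel_contribution(slices["education"], alpha) + config.gamma_u * U \
        + rng.normal(0.0, np.sqrt(var_eps_e), size=n)

    pheno = {"education": E}
    latent = {}
    for med in MEDIATORS:
        r2 = config.mediator_instrument_r2[med]
        theta = config.theta[med]
        delta = config.delta_u[med]
        a_med = a_meds[med]
        var_eps = (
            1.0 - theta**2 - r2 - delta**2 - 2 * theta * delta * config.gamma_u
        )
        if var_eps <= 0:
            raise ValueError(f"infeasible variance budget for mediator {med!r}")
        M = theta * E + panel_contribution(slices[med], a_med) + delta * U \
            + rng.normal(0.0, np.sqrt(var_eps), size=n)
        latent[med] = M
        pheno[f"{med}_latent"] = M
        noise_var = 1.0 / config.reliability[med] - 1.0
        pheno[med] = M + rng.normal(0.0, np.sqrt(noise_var), size=n) if noise_var > 0 else M.copy()

    eta = (
        math.log(config.outcome_prevalence / (1 - config.outcome_prevalence))
        + config.beta_direct * E
        + sum(config.beta_mediator[m_] * latent[m_] for m_ in MEDIATORS)
        + config.phi_u * U
    )
    if pleio_idx is not None:
        cols = np.arange(total_snps)[slices["education"]][pleio_idx]
        eta = eta + (G32[:, cols] - 2 * mafs[cols]) @ np.full(
            len(pleio_idx), config.pleiotropy_effect, dtype=np.float32
        )
    Y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)

    pheno["outcome"] = Y
    # decorative covariates exercised by the API, causally inert
    pheno["age"] = rng.normal(57.0, 8.0, size=n)
    pheno["sex"] = rng.integers(0, 2, size=n)
    phenotypes = pd.DataFrame(pheno)

    snp_ids = [s for t in PANELS for s in panel_snp_ids(config, t)]
    snp_info = pd.DataFrame({
        "SNP": snp_ids,
        "CHR": [str(i + 1) for i, t in enumerate(PANELS) for _ in range(m)],
        "BP": [1_000_000 * (k + 1) for _ in PANELS for k in range(m)],
        "EA": ea,
        "OA": oa,
        "MAF": mafs.astype(float),
    })
    cohort = Cohort(G, phenotypes, snp_ids, snp_info)
    cohort._g32 = G32  # pre-warm the float32 cache used by the scans
    return cohort, SimulationTruth.from_config(config)


# ---------------------------------------------------------------------------
# GWAS on the cohort
# ---------------------------------------------------------------------------

def _linear_gwas(G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None):
    """Vectorised per-SNP simple linear regression (after FWL residualisation).

    Accumulations run in the dtype of ``G`` (float32 for large scans,
    float64 for small ones where exact agreement with a per-SNP fit
    matters).
    """
    n = len(y)
    y = y.astype(G.dtype, copy=True)
    df_adj = 2
    if covariates is not None:
        X = np.column_stack([np.ones(n), covariates]).astype(G.dtype)
        Q, _ = np.linalg.qr(X)
        y = y - Q @ (Q.T @ y)
        G = G - Q @ (Q.T @ G)
        df_adj = 2 + covariates.shape[1]
        sxx = np.einsum("ij,ij->j", G, G).astype(np.float64)
        sxy = (y @ G).astype(np.float64)
        syy = float(y @ y)
    else:
        # moment form: centring y alone makes the cross-product exact and
        # avoids materialising a centred copy of the dosage matrix
        y = y - y.mean()
        gsum = G.sum(axis=0, dtype=np.float64)
        g2sum = np.einsum("ij,ij->j", G, G).astype(np.float64)
        sxx = g2sum - gsum**2 / n
        sxy = (y @ G).astype(np.float64)
        syy = float(y @ y)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - df_adj)
        se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=n - df_adj)
    return beta, se, p


def _logistic_gwas_counts(G: np.ndarray, y: np.ndarray):
    """Exact per-SNP logistic regression for integer dosages via sufficient stats.

    With a dosage taking values {0,1,2} the per-SNP logistic likelihood
    depends only on the case/control counts within each genotype class, so
    Newton–Raphson runs on a 3 x m array. Agreement with a conventional
    per-SNP logistic fit is covered by tests.
    """
    n, m = G.shape
    y32 = y.astype(np.float32)
    g1 = G == 1
    g2 = G == 2
    n1 = g1.sum(axis=0).astype(float)
    n2 = g2.sum(axis=0).astype(float)
    n0 = n - n1 - n2
    c1 = (y32 @ g1).astype(float)
    c2 = (y32 @ g2).astype(float)
    c0 = float(y32.sum()) - c1 - c2
    counts = np.stack([n0, n1, n2])
    cases = np.stack([c0, c1, c2])
    x = np.array([0.0, 1.0, 2.0])[:, None]
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    det = np.ones(m)
    h00 = np.ones(m)
    for _ in range(40):
        eta = a + x * b
        p = 1.0 / (1.0 + np.exp(-eta))
        r = cases - counts * p
        w = counts * p * (1 - p)
        s0 = r.sum(axis=0)
        s1 = (x * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0)
        det = h00 * h11 - h01 * h01
        da = (h11 * s0 - h01 * s1) / det
        db = (h00 * s1 - h01 * s0) / det
        a += da
        b += db
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < 1e-12:
            break
    se = np.sqrt(h00 / det)
    z = b / se
    p_val = 2 * stats.norm.sf(np.abs(z))
    return b, se, p_val


def compute_gwas_summaries(
    cohort: Cohort,
    trait_col: str,
    covariates: Sequence[str] = (),
    snp_ids: Sequence[str] | None = None,
) -> SummarySet:
    """Per-SNP association scan of one phenotype against the cohort dosages.

    Continuous traits use linear regression (vectorised across SNPs); a
    binary trait uses exact per-SNP logistic regression. Constant dosage
    columns are skipped with a log entry. Effect-allele frequency is the
    mean dosage / 2; alleles and positions come from the cohort's
    ``snp_info``.
    """
    ids = list(snp_ids) if snp_ids is not None else list(cohort.snp_ids)
    cols: list[int] | slice = [cohort._snp_index[s] for s in ids]
    if cols and cols == list(range(cols[0], cols[-1] + 1)):
        cols = slice(cols[0], cols[-1] + 1)  # view, not copy
    G = cohort.genotypes[:, cols]
    y = cohort.phenotypes[trait_col].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    cov = (
        cohort.phenotypes[list(covariates)].to_numpy(dtype=float) if covariates else None
    )
    big = G.size > 2_000_000  # single precision is ample for large scans
    if binary and cov is None and np.issubdtype(np.asarray(G).dtype, np.integer):
        beta, se, p = _logistic_gwas_counts(G, y)
        eaf = cohort.genotypes_float32[:, cols].mean(axis=0).astype(float) / 2
    elif binary:
        beta, se, p = _logistic_gwas_batched(G.astype(np.float64), y, cov)
        eaf = np.asarray(G, dtype=float).mean(axis=0) / 2
    else:
        Gf = cohort.genotypes_float32[:, cols] if big else G.astype(np.float64)
        eaf = Gf.mean(axis=0).astype(float) / 2
        beta, se, p = _linear_gwas(Gf, y, cov)
    info = None
    if cohort.snp_info is not None:
        info = cohort.snp_info.set_index("SNP")
    sset = SummarySet(trait_col)
    n = cohort.n
    for j, sid in enumerate(ids):
        if not np.isfinite(beta[j]) or not se[j] > 0:
            sset.skipped.append((sid, "constant_dosage_or_degenerate_fit"))
            continue
        if info is not None and sid in info.index:
            row = info.loc[sid]
            rec = SnpAssociation(
                snp_id=sid, chrom=str(row["CHR"]), pos=int(row["BP"]),
                effect_allele=str(row["EA"]), other_allele=str(row["OA"]),
                eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
                pvalue=float(max(p[j], 5e-324)), n=float(n),
            )
        else:
            rec = SnpAssociation(
                snp_id=sid, effect_allele="A", other_allele="G",
                eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
                pvalue=float(max(p[j], 5e-324)), n=float(n),
            )
        sset.add(rec)
    return sset


def _logistic_gwas_batched(G: np.ndarray, y: np.ndarray, cov: np.ndarray | None, chunk: int = 64):
    """Chunked Newton logistic scan for fractional dosages / covariates."""
    import statsmodels.api as sm

    n, m = G.shape
    beta = np.empty(m)
    se = np.empty(m)
    p = np.empty(m)
    base = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    for j in range(m):
        X = np.column_stack([base[:, :1], G[:, j], base[:, 1:]])
        try:
            res = sm.Logit(y, X).fit(disp=0)
            beta[j], se[j], p[j] = res.params[1], res.bse[1], res.pvalues[1]
        except Exception:
            beta[j], se[j], p[j] = np.nan, 0.0, 1.0
    return beta, se, p


def split_sample(cohort: Cohort, fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive random partition of the cohort (seeded)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = cohort.n
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    return cohort.take(np.sort(perm[:k])), cohort.take(np.sort(perm[k:]))
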