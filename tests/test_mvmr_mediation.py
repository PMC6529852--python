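"""Multivariable MR and the mediation algebra."""
import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate.mr_estimators import ivw_fixed
from mrmediate.mvmr_mediation import (
    Effect,
    MultiHarmonisedSet,
    MvmrRow,
    combined_difference,
    harmonise_multi,
    mvmr_fit,
    product_indirect,
    proportion_mediated,
    two_step_mediation,
)

from conftest import make_harmonised, make_record, make_set


def make_multi(bx, sx, by, sy, names=("education", "mediator")):
    rows = [
        MvmrRow(f"rs{i}", np.asarray(bxi, float), np.asarray(sxi, float),
                float(byi), float(syi))
        for i, (bxi, sxi, byi, syi) in enumerate(zip(bx, sx, by, sy))
    ]
    return MultiHarmonisedSet(list(names), rows=rows)


# ---------------------------------------------------------------------------
# mvmr_fit
# ---------------------------------------------------------------------------

def test_mvmr_single_exposure_equals_regression_form_ivw(rng):
    k = 10
    bx = rng.uniform(0.05, 0.3, k)
    by = 0.4 * bx + rng.normal(0, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    multi = make_multi(bx[:, None], np.full((k, 1), 0.01), by, sy, names=["education"])
    h = make_harmonised(bx, np.full(k, 0.01), by, sy)
    fit = mvmr_fit(multi)
    assert fit.coefficients["education"][0] == pytest.approx(ivw_fixed(h).beta, rel=1e-10)


def test_mvmr_exact_solve_on_orthogonal_columns():
    bx = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    by = 0.3 * bx[:, 0] - 0.2 * bx[:, 1]
    multi = make_multi(bx, np.full_like(bx, 0.01), by, np.full(5, 0.01))
    fit = mvmr_fit(multi)
    assert fit.coefficients["education"][0] == pytest.approx(0.3, abs=1e-12)
    assert fit.coefficients["mediator"][0] == pytest.approx(-0.2, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_mvmr_matches_normal_equation_oracle(seed):
    rng = np.random.default_rng(seed)
    k, p = 8, 2
    bx = rng.normal(0.1, 0.05, (k, p))
    by = bx @ np.array([0.3, -0.2]) + rng.normal(0, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    multi = make_multi(bx, np.full((k, p), 0.01), by, sy)
    fit = mvmr_fit(multi)
    wls = sm.WLS(by, bx, weights=1 / sy**2).fit()
    assert fit.coefficients["education"][0] == pytest.approx(float(wls.params[0]), rel=1e-10)
    assert fit.coefficients["mediator"][0] == pytest.approx(float(wls.params[1]), rel=1e-10)


def test_mvmr_rank_deficiency_names_collinear_exposures(rng):
    k = 6
    col = rng.uniform(0.05, 0.3, k)
    bx = np.column_stack([col, 2 * col])
    multi = make_multi(bx, np.full((k, 2), 0.01), col, np.full(k, 0.01))
    with pytest.raises(ValueError, match="education.*mediator"):
        mvmr_fit(multi)


def test_mvmr_zero_mediator_column_returns_education_ivw(rng):
    """An all-zero mediator column carries no signal: the education
    coefficient equals single-exposure IVW and the mediator reports null."""
    k = 9
    bx1 = rng.uniform(0.05, 0.3, k)
    by = 0.5 * bx1 + rng.normal(0, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    multi = make_multi(
        np.column_stack([bx1, np.zeros(k)]), np.full((k, 2), 0.01), by, sy
    )
    fit = mvmr_fit(multi)
    h = make_harmonised(bx1, np.full(k, 0.01), by, sy)
    assert fit.coefficients["education"][0] == pytest.approx(ivw_fixed(h).beta, rel=1e-10)
    assert fit.coefficients["mediator"][0] == 0.0
    assert fit.coefficients["mediator"][1] == np.inf


def test_mvmr_needs_more_snps_than_exposures():
    multi = make_multi(np.eye(2), np.full((2, 2), 0.01), [0.1, 0.2], [0.01, 0.01])
    with pytest.raises(ValueError, match="more SNPs"):
        mvmr_fit(multi)


# ---------------------------------------------------------------------------
# product / proportion algebra
# ---------------------------------------------------------------------------

def test_product_indirect_sobel():
    eff = product_indirect(Effect(-0.2, 0.05), Effect(0.5, 0.1))
    assert eff.beta == pytest.approx(-0.1)
    assert eff.se == pytest.approx(np.sqrt(0.0004 + 0.000625), rel=1e-12)
    # oracle: numeric gradient propagation of f(a, b) = a*b
    grad = np.array([0.5, -0.2])
    assert eff.se == pytest.approx(
        float(np.sqrt(grad[0] ** 2 * 0.05**2 + grad[1] ** 2 * 0.1**2)), rel=1e-10
    )


def test_product_indirect_null_a():
    eff = product_indirect(Effect(0.0, 0.05), Effect(0.5, 0.1))
    assert eff.beta == 0.0
    assert eff.se == pytest.approx(0.5 * 0.05)


def test_product_indirect_identity_mediator():
    a = Effect(-0.2, 0.05)
    eff = product_indirect(a, Effect(1.0, 0.0))
    assert eff.beta == pytest.approx(a.beta)
    assert eff.se == pytest.approx(a.se)


def test_proportion_simple_ratio():
    p = proportion_mediated(Effect(-0.1, 0.01), Effect(-0.5, 0.02))
    assert p.point == pytest.approx(0.2)


def test_proportion_forced_identity():
    p = proportion_mediated(Effect(-0.5, 0.05), Effect(-0.5, 0.05))
    assert p.point == pytest.approx(1.0)
    assert p.se == pytest.approx(np.sqrt(2) * 0.05 / 0.5, rel=1e-10)


def test_proportion_null_total_errors():
    with pytest.raises(ZeroDivisionError):
        proportion_mediated(Effect(0.1, 0.01), Effect(0.0, 0.02))


@pytest.mark.parametrize("c", [2.0, -3.0, 0.1])
def test_proportion_scale_invariance(c):
    base = proportion_mediated(Effect(-0.1, 0.02), Effect(-0.4, 0.05))
    scaled = proportion_mediated(Effect(-0.1 * c, 0.02 * abs(c)), Effect(-0.4 * c, 0.05 * abs(c)))
    assert scaled.point == pytest.approx(base.point, rel=1e-12)
    assert scaled.se == pytest.approx(base.se, rel=1e-12)


def test_proportion_ci_not_truncated():
    p = proportion_mediated(Effect(0.3, 0.5), Effect(0.3, 0.01))
    assert p.ci_high > 1 or p.ci_low < 0


def test_proportion_bootstrap_samples_path(rng):
    samples = rng.normal(0.2, 0.05, 500)
    p = proportion_mediated(
        Effect(0.1, 0.01), Effect(0.5, 0.02),
        se_method="bootstrap_samples", bootstrap_samples=samples,
    )
    assert p.se == pytest.approx(float(np.std(samples, ddof=1)))
    assert p.ci_low == pytest.approx(float(np.percentile(samples, 2.5)))


# ---------------------------------------------------------------------------
# combined difference
# ---------------------------------------------------------------------------

def _direct(beta, se, name="education"):
    from mrmediate.mvmr_mediation import MvmrEstimate

    return MvmrEstimate({name: (beta, se, 0.5)}, n_snps=10)


def test_difference_no_mediation():
    est = combined_difference(Effect(-0.5, 0.02), _direct(-0.5, 0.03))
    assert est.proportion.point == pytest.approx(0.0)


def test_difference_full_mediation():
    est = combined_difference(Effect(-0.5, 0.02), _direct(0.0, 0.03))
    assert est.proportion.point == pytest.approx(1.0)


def test_difference_printed_magnitudes():
    est = combined_difference(Effect(-0.462, 0.02), _direct(-0.296, 0.03))
    assert est.proportion.point == pytest.approx((-0.462 + 0.296) / -0.462, rel=1e-12)
    assert est.proportion.point == pytest.approx(0.359, abs=5e-4)


# ---------------------------------------------------------------------------
# multi-harmonisation + two-step on constructed summary data
# ---------------------------------------------------------------------------

def _structured_summary_sets(rng, k_edu=40, k_med=40, a=-0.3, b=0.4, direct=-0.2,
                             noise=0.002):
    """Summary statistics of an exact linear system:
    education SNPs -> education -> mediator -> outcome (+ direct path)."""
    alpha = rng.uniform(0.02, 0.08, k_edu)          # SNP -> education
    gamma = rng.uniform(0.02, 0.08, k_med)          # SNP -> mediator (own panel)
    edu_recs, med_recs, out_recs = [], [], []
    for i in range(k_edu):
        sid = f"e{i}"
        bx = alpha[i] + rng.normal(0, noise)
        bm = a * alpha[i] + rng.normal(0, noise)
        byy = (direct + a * b) * alpha[i] + rng.normal(0, noise)
        edu_recs.append(make_record(sid, beta=bx, se=noise, pos=i + 1))
        med_recs.append(make_record(sid, beta=bm, se=noise, pos=i + 1))
        out_recs.append(make_record(sid, beta=byy, se=noise, pos=i + 1))
    for i in range(k_med):
        sid = f"m{i}"
        edu_recs.append(make_record(sid, beta=rng.normal(0, noise), se=noise, pos=100 + i))
        med_recs.append(make_record(sid, beta=gamma[i] + rng.normal(0, noise), se=noise, pos=100 + i))
        out_recs.append(make_record(sid, beta=b * gamma[i] + rng.normal(0, noise), se=noise, pos=100 + i))
    return (
        make_set(edu_recs, "education"),
        make_set(med_recs, "mediator"),
        make_set(out_recs, "outcome"),
        [f"e{i}" for i in range(k_edu)],
        [f"m{i}" for i in range(k_med)],
    )


def test_harmonise_multi_drops_snps_missing_an_exposure(rng):
    edu, med, out, e_ids, m_ids = _structured_summary_sets(rng)
    del med.records["e0"]
    multi = harmonise_multi([edu, med], out, snp_ids=e_ids + m_ids)
    assert len(multi) == len(e_ids) + len(m_ids) - 1
    assert ("e0", "missing_in_mediator") in multi.dropped


def test_two_step_recovers_known_proportion(rng):
    """Truth: T = direct + a*b = -0.32, P = ab/T = 0.375."""
    edu, med, out, e_ids, m_ids = _structured_summary_sets(rng)
    est = two_step_mediation(edu, med, out, e_ids, m_ids)
    assert est.total.beta == pytest.approx(-0.32, abs=0.02)
    assert est.components["a"].beta == pytest.approx(-0.3, abs=0.02)
    assert est.components["b"].beta == pytest.approx(0.4, abs=0.03)
    assert est.proportion.point == pytest.approx(0.375, abs=0.03)
    assert est.indirect.beta == pytest.approx(
        est.components["a"].beta * est.components["b"].beta, rel=1e-12
    )


def test_two_step_null_mediator_pathway(rng):
    edu, med, out, e_ids, m_ids = _structured_summary_sets(rng, a=0.0)
    est = two_step_mediation(edu, med, out, e_ids, m_ids)
    assert est.proportion.point == pytest.approx(0.0, abs=0.05)
    assert est.proportion.ci_low < 0 < est.proportion.ci_high


def test_product_and_difference_agree_in_linear_system():
    """With one mediator and no interactions the two constructions target
    the same estimand; their means agree over replicates."""
    rng = np.random.default_rng(3)
    diffs = []
    for _ in range(200):
        edu, med, out, e_ids, m_ids = _structured_summary_sets(
            rng, k_edu=15, k_med=15, noise=0.004
        )
        prod = two_step_mediation(edu, med, out, e_ids, m_ids)
        multi = harmonise_multi([edu, med], out, snp_ids=e_ids + m_ids)
        diff = combined_difference(
            ivw_fixed(__import__("mrmediate.summary_core", fromlist=["harmonise"]).harmonise(
                edu.subset(e_ids), out)),
            mvmr_fit(multi), exposure="education",
        )
        diffs.append(prod.proportion.point - diff.proportion.point)
    assert np.mean(diffs) == pytest.approx(0.0, abs=0.01)
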