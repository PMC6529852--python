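import numpy as np
import pytest

from mrmediate.summary_core import HarmonisedRow, HarmonisedSet, SnpAssociation, SummarySet


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3,
                chrom="1", pos=1000, pvalue=1e-8, n=1000.0):
    return SnpAssociation(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


def make_set(records, trait="trait"):
    sset = SummarySet(trait)
    for rec in records:
        sset.add(rec)
    return sset


def make_harmonised(bx, sx, by, sy, exposure="exp", outcome="out"):
    rows = [
        HarmonisedRow(f"rs{i}", float(a), float(b), float(c), float(d))
        for i, (a, b, c, d) in enumerate(zip(bx, sx, by, sy))
    ]
    return HarmonisedSet(exposure, outcome, rows=rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_harmonised(rng, k=8, slope=0.5, intercept=0.0, noise=0.01):
    bx = rng.uniform(0.05, 0.3, k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.005, 0.03, k)
    by = intercept + slope * bx + rng.normal(0, noise, k)
    return make_harmonised(bx, sx, by, sy)
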