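import numpy as np
import pytest

from patloc.ldcred import GenotypePanel
from patloc.sumstats import SumStatRecord, SumStatTable, VariantKey


def make_record(
    chrom="1", pos=1000, ea="A", oa="G", beta=0.1, se=0.02, p=1e-8,
    eaf=0.3, n=10_000.0, **kwargs,
):
    return SumStatRecord(
        key=VariantKey(chrom, pos, ea, oa), beta=beta, se=se, p=p, eaf=eaf, n=n, **kwargs
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def toy_table():
    """Three-variant quantitative table on chr1."""
    records = [
        make_record(pos=1000, ea="A", oa="G", beta=0.10, p=1e-10),
        make_record(pos=2000, ea="C", oa="T", beta=-0.05, p=1e-6),
        make_record(pos=3000, ea="G", oa="C", beta=0.08, p=1e-4, eaf=0.2),
    ]
    return SumStatTable(records, trait_type="quantitative")


@pytest.fixture
def correlated_panel():
    """Panel of 4 variants with controlled pairwise correlation.

    v0 and v1 are identical columns (r2 = 1); v2 is a noisy copy of v0
    (r2 about 0.5); v3 is independent.
    """
    rng = np.random.default_rng(11)
    n = 2000
    base = rng.binomial(2, 0.4, size=n).astype(float)
    noisy = np.where(rng.random(n) < 0.45, rng.binomial(2, 0.4, size=n), base).astype(float)
    indep = rng.binomial(2, 0.4, size=n).astype(float)
    keys = [
        VariantKey("1", 1000, "A", "G"),
        VariantKey("1", 11_000, "A", "G"),
        VariantKey("1", 21_000, "A", "G"),
        VariantKey("1", 31_000, "A", "G"),
    ]
    return GenotypePanel(keys, np.column_stack([base, base, noisy, indep]))
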