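import numpy as np
import pandas as pd
import pytest

from seqblup.panels import GenotypeMatrix, VariantPanel
from seqblup.simdata import SimConfig, TraitConfig, simulate_genotypes


def make_panel(m, chrom="1", vtype=None, spacing=1000):
    vtype = vtype if vtype is not None else ["SNP"] * m
    pos = [(i + 1) * spacing for i in range(m)]
    return VariantPanel(
        pd.DataFrame(
            {
                "variant_id": [f"{chrom}:{p}:A:{'G' if t == 'SNP' else 'AT'}"
                               for p, t in zip(pos, vtype)],
                "chrom": chrom,
                "pos": pos,
                "vtype": vtype,
                "ref": "A",
                "alt": ["G" if t == "SNP" else "AT" for t in vtype],
            }
        )
    )


def make_gm(dosage, **kw):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        [f"s{i:03d}" for i in range(n)], make_panel(m, **kw), dosage
    )


def random_gm(n, m, rng, p_range=(0.1, 0.5), missing_rate=0.0):
    """Unstructured binomial genotypes, independent variants."""
    p = rng.uniform(*p_range, m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    if missing_rate:
        dosage[rng.random((n, m)) < missing_rate] = np.nan
    return make_gm(dosage)


@pytest.fixture(scope="session")
def sim_gm():
    """Moderate structured dataset shared by read-only tests."""
    cfg = SimConfig(
        n_individuals=300,
        n_snp=600,
        n_indel=150,
        fst=0.05,
        block_size=15,
        within_block_corr=0.7,
        missing_rate=0.02,
        seed=11,
    )
    gm, _ = simulate_genotypes(cfg)
    return gm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
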