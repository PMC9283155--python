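import numpy as np
import pandas as pd
import pytest

from prs_gxe import SimConfig, simulate_study
from prs_gxe.containers import GenotypeMatrix


def make_genotypes(dosages, positions=None, chrom="1", ref="A", alt="G", ids=None):
    """Hand-built genotype matrix for small deterministic fixtures."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if ids is None:
        ids = [f"v{j}" for j in range(m)]
    ref = [ref] * m if isinstance(ref, str) else list(ref)
    alt = [alt] * m if isinstance(alt, str) else list(alt)
    variants = pd.DataFrame(
        {"id": ids, "chrom": [chrom] * m, "pos": positions, "ref": ref, "alt": alt}
    )
    return GenotypeMatrix(
        dosages=d, samples=[f"s{i}" for i in range(n)], variants=variants
    )


def make_weights(ids, betas, ps, effect="G", other="A", chrom="1", positions=None):
    m = len(ids)
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    effect = [effect] * m if isinstance(effect, str) else list(effect)
    other = [other] * m if isinstance(other, str) else list(other)
    return pd.DataFrame(
        {
            "snp": ids,
            "chrom": [chrom] * m,
            "pos": positions,
            "effect_allele": effect,
            "other_allele": other,
            "beta": betas,
            "p": ps,
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by read-only tests."""
    return simulate_study(
        SimConfig(n_samples=400, n_blocks=10, snps_per_block=3, seed=11)
    )


@pytest.fixture(scope="session")
def clean_study():
    """Simulated study without genotype missingness (exact-score tests)."""
    return simulate_study(
        SimConfig(n_samples=500, n_blocks=10, snps_per_block=3, seed=13, missing_rate=0.0)
    )
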