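import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carrotdom.genotypes import MISSING, GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_genotype_matrix(
    rng,
    n_loci=30,
    samples_per_group=(5, 5),
    group_names=("cultivated", "wild"),
    missing_rate=0.0,
):
    """Random biallelic (A/G) matrix with group labels for oracle tests."""
    n_samples = sum(samples_per_group)
    pair = np.array([0, 2])  # A and G
    codes = np.empty((n_loci, n_samples, 2), dtype=np.int8)
    for i in range(n_loci):
        p = rng.uniform(0.05, 0.95)
        draws = rng.choice(pair[:2], size=(n_samples, 2), p=[p, 1 - p])
        codes[i] = np.sort(draws, axis=1)
    if missing_rate > 0:
        miss = rng.random((n_loci, n_samples)) < missing_rate
        codes[miss] = MISSING
    samples, groups = [], {}
    for gname, count in zip(group_names, samples_per_group):
        for j in range(count):
            s = f"{gname[:4]}{j + 1}"
            samples.append(s)
            groups[s] = gname
    loci = [("sim", i + 1) for i in range(n_loci)]
    return GenotypeMatrix(codes, loci, samples, groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
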