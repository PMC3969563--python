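import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from radpop.genotypes import NO_INDEL, GenotypeMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(
    G,
    positions=None,
    chrom="1",
    species=None,
    location=None,
    depth=30,
    qual=99.0,
    near_indel=NO_INDEL,
    extra_monomorphic=0,
) -> GenotypeMatrix:
    """Build a small in-memory genotype matrix for tests."""
    G = np.asarray(G, dtype=np.int8)
    n, s = G.shape
    positions = np.arange(1, s + 1) * 10 if positions is None else np.asarray(positions)
    sites = pd.DataFrame({
        "chrom": chrom if isinstance(chrom, str) else list(chrom),
        "pos": positions,
        "ref": "A",
        "alt": "T",
        "qual": qual if np.ndim(qual) else float(qual),
        "near_indel_bp": near_indel,
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "species": species if species is not None else ["sp"] * n,
        "location": location if location is not None else ["loc"] * n,
    })
    depth_arr = None if depth is None else np.full((n, s), depth, dtype=np.int32)
    if np.ndim(depth) == 2:
        depth_arr = np.asarray(depth, dtype=np.int32)
    return GenotypeMatrix(sites=sites, samples=samples, G=G, depth=depth_arr,
                          extra_monomorphic=extra_monomorphic)


@pytest.fixture
def two_pop_matrix():
    """10 + 10 diploids, hand-set allele frequencies p1 = 0.7, p2 = 0.3."""
    # pop1: 5 hom-alt, 4 het, 1 hom-ref  -> p = 0.7, Hobs = 0.4
    # pop2: 1 hom-alt, 4 het, 5 hom-ref  -> p = 0.3, Hobs = 0.4
    col = np.array([2] * 5 + [1] * 4 + [0] + [2] + [1] * 4 + [0] * 5)
    G = np.tile(col[:, None], (1, 3))
    return make_matrix(
        G,
        species=["p1"] * 10 + ["p2"] * 10,
        location=["x"] * 10 + ["y"] * 10,
    )
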