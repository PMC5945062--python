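import numpy as np
import pytest

from grntopo import (
    PowerLawModel,
    SyntheticGRNConfig,
    build_grn,
    generate_insilico_grn,
)
from grntopo.network import PDIRecord, degree_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def yeast_scale_grn():
    """Synthetic GRN at the scale of the budding-yeast complete network:
    ~60k interactions on a ~5.3k-gene genome with 5% TF-coding genes,
    out-degree exponent 2."""
    cfg = SyntheticGRNConfig(
        target_exponent=2.0, n_edges=60_000, n_nodes=5301, tf_fraction=0.05,
        seed=424242,
    )
    return generate_insilico_grn(cfg)


@pytest.fixture(scope="session")
def yeast_scale_outdegrees(yeast_scale_grn):
    return degree_sequence(yeast_scale_grn, "out")


@pytest.fixture
def star_grn():
    """One TF binding ten targets."""
    recs = [PDIRecord("TF1", f"g{i}") for i in range(10)]
    return build_grn(recs)


@pytest.fixture
def toy_weighted_grn():
    """20 TFs with out-degrees 1..20 over distinct targets (210 edges)."""
    recs = []
    t = 0
    for i in range(1, 21):
        for _ in range(i):
            recs.append(PDIRecord(f"TF{i:02d}", f"g{t:03d}"))
            t += 1
    return build_grn(recs)


@pytest.fixture
def alpha2_model():
    return PowerLawModel(alpha=2.0, kmin=1, kmax=10_000)
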