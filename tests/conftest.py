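import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cernakit as ck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design():
    return ck.generate_design(3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """Small planted dataset shared by read-only tests: counts, truth, rpkm, targets."""
    counts, truth = ck.generate_counts(
        small_design,
        n_per_biotype={"mRNA": 120, "lncRNA": 60, "circRNA": 40, "miRNA": 30},
        n_de=30,
        de_log2fc=2.0,
        seed=11,
        n_triplets=4,
    )
    rpkm = ck.compute_rpkm(counts)
    targets = ck.generate_target_map(
        counts, n_mirna=30, targets_per_mirna=8, triplets=truth.triplets, seed=11
    )
    return {"counts": counts, "truth": truth, "rpkm": rpkm, "targets": targets}


@pytest.fixture(scope="session")
def small_de(small_dataset, small_design):
    return ck.call_de(small_dataset["rpkm"], small_design, "TG")


def rng_seeds(base: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(base).integers(0, 2**31 - 1, size=n)]
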