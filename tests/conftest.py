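import numpy as np
import pytest

import cghscreen as cg


@pytest.fixture(scope="session")
def demo():
    """The packaged 1000-probe / 8-pair demonstration study with two
    planted case-only events of known truth."""
    return cg.demo_study()


@pytest.fixture(scope="session")
def null_study():
    """48 pairs, 1000 probes, no planted events."""
    return cg.simulate_study(
        n_probes=1000,
        n_pairs=48,
        chromosome_lengths={"1": 120e6, "2": 100e6, "3": 80e6},
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_flat_map(n: int, chrom: str = "1", spacing: int = 1000) -> cg.ProbeMap:
    """Evenly spaced probes on one chromosome, handy for unit tests."""
    return cg.ProbeMap(
        probe_id=np.array([f"p{i}" for i in range(n)], dtype=object),
        chromosome=np.array([chrom] * n, dtype=object),
        position=np.arange(1, n + 1, dtype=np.int64) * spacing,
    )
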