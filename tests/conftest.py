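import numpy as np
import pytest

from cnsmooth.crossval import compute_error_data
from cnsmooth.synthetic import default_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The standard seeded synthetic benchmark (profiles, truth, annotations)."""
    return default_benchmark(seed=1)


@pytest.fixture(scope="session")
def benchmark_error_data(benchmark):
    """Per-annotation verdicts of cghseg.k on the benchmark, computed once."""
    profiles, _, annotations = benchmark
    return compute_error_data(profiles, annotations, "cghseg.k")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
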