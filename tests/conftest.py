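import pytest

from duspkin import SolverOptions, build_parameters

D5_GRID = [1.0, 10.0, 20.0, 50.0, 100.0, 500.0]


@pytest.fixture(scope="session")
def ref_params():
    """Reference parameterization: all rates/weights 1, hill 0.6,
    herceptin 100, totals 100."""
    return build_parameters({})


@pytest.fixture(scope="session")
def fast_opts():
    """Coarser output grid for tests that integrate many times."""
    return SolverOptions(n_points=101)
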