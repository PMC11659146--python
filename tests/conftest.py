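import pytest

from hcc_cea import default_bundle, run_base_case


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def base_outcomes(bundle):
    """Deterministic partitioned-survival base case, both arms."""
    return run_base_case(bundle)
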