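import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def boundaries():
    from class1scan.benchmark import measure_decision_boundaries

    return measure_decision_boundaries(seed=0)


@pytest.fixture(scope="session")
def bench():
    from class1scan.benchmark import run_benchmark
    from class1scan.synthetic import SynthConfig

    return run_benchmark(SynthConfig(seed=7))
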