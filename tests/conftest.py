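import hypothesis
import pytest

from crisprdyn import ChemostatEnv

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def env() -> ChemostatEnv:
    """Default habitat: the shared parameter set of all simulation figures
    (A=50 µg/ml, w=0.2/hr, k=0.25 µg/ml, e=5e-7 µg)."""
    return ChemostatEnv()


@pytest.fixture(scope="session")
def preset_runs():
    """Memoized preset runner: each named preset is simulated at most once
    per test session and the (trajectory, summary, echo) triple is shared."""
    from crisprdyn.scenarios import run_preset

    cache = {}

    def get(name: str):
        if name not in cache:
            cache[name] = run_preset(name)
        return cache[name]

    return get
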