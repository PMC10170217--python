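import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid_patch():
    """10x10 triangulated grid patch with its ROI edges."""
    from magmap.simulate import make_patch

    return make_patch(10)


@pytest.fixture(scope="session")
def run_T():
    from magmap.stimulus import build_run

    return build_run("T", seed=0)


@pytest.fixture(scope="session")
def run_C():
    from magmap.stimulus import build_run

    return build_run("C", seed=0)


@pytest.fixture(scope="session")
def probe_seqs():
    """One run per condition, the joint-fit probe ensemble."""
    from magmap.stimulus import build_run

    return [build_run(c, seed=i) for i, c in enumerate("TNCI")]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
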