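import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_construct():
    from coremature.synth import make_demo_construct

    return make_demo_construct()


@pytest.fixture(scope="session")
def ideal_geometry():
    from coremature.synth import SyntheticGeometrySpec, gen_ring_geometry

    return gen_ring_geometry(SyntheticGeometrySpec())


@pytest.fixture(scope="session")
def small_alignment():
    from coremature.synth import SyntheticAlignmentSpec, gen_alignment

    return gen_alignment(SyntheticAlignmentSpec(n_sequences=40, seed=11))
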