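import numpy as np
import pytest

from pubicorridor import (PipelineConfig, PubisPhantomSpec, StripPhantomSpec,
                          analyze_hemipelvis, generate_pubis_phantom,
                          generate_strip_phantom)


@pytest.fixture(scope="session")
def strip_default():
    """T=20, H=60, W=40 slab with entry 10 mm from the anterior wall."""
    return generate_strip_phantom(StripPhantomSpec())


@pytest.fixture(scope="session")
def pubis_default():
    return generate_pubis_phantom(PubisPhantomSpec())


@pytest.fixture(scope="session")
def pubis_nohole():
    from dataclasses import replace

    return generate_pubis_phantom(replace(PubisPhantomSpec(),
                                          obturator_radius=0.0))


@pytest.fixture(scope="session")
def pubis_analysis(pubis_default):
    """Full corridor analysis of the default phantom (accurate profile);
    session-scoped because several tests read different parts of it."""
    mesh, lm = pubis_default
    return analyze_hemipelvis(mesh, lm, PipelineConfig())


@pytest.fixture(scope="session")
def fast_config():
    return PipelineConfig.fast()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
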