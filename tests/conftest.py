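import numpy as np
import pytest

import placentadce as p
from placentadce import io_preprocess as iop
from placentadce import perfusion as perf


@pytest.fixture(scope="session")
def quiet_spec() -> p.PhantomSpec:
    """Noiseless, motionless phantom at the default study grid."""
    return p.PhantomSpec(noise_sigma=0.0, motion=p.MotionSpec(enabled=False), seed=7)


@pytest.fixture(scope="session")
def quiet_session(quiet_spec):
    """Synthesized noiseless/motionless session (series, vfa pre/post, truth)."""
    return p.synthesize_dce(quiet_spec)


@pytest.fixture(scope="session")
def quiet_perfusion(quiet_session):
    """Perfusion map of the noiseless session via the standard chain."""
    series, _pre, _post, truth = quiet_session
    den = iop.temporal_denoise(series)
    aif = perf.extract_aif(den, truth.label_map)
    clean = den.with_data(iop.spatial_median3(den.data))
    ss = perf.steepest_slope_map(clean)
    return perf.perfusion_map(ss, aif), ss, aif, truth


@pytest.fixture(scope="session")
def moving_session():
    """Default E17.5 session: 2% noise, phasic motion at default prevalence."""
    spec = p.PhantomSpec(seed=3)
    return p.synthesize_dce(spec), spec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
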