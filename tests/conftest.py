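import hypothesis
import pytest
from hypothesis import strategies as st

import ptrcell as pc

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def caption_params():
    """Reference parameter set with all three molecular volumes equal."""
    return pc.baseline_parameters(q=1.0, f_R=0.1)


@pytest.fixture
def bulk_volume_params():
    """Reference rates with the bulk volume law V = v_P (P + R)."""
    return pc.baseline_parameters(q=1.0, f_R=0.1, v_T=0.0)


@pytest.fixture
def precursor_volume_params():
    """Reference rates with precursor-dominated volume V = v_P P."""
    return pc.baseline_parameters(q=1.0, f_R=0.1, v_T=0.0, v_R=0.0)


@pytest.fixture(scope="session")
def random_growing_sets():
    """20 seeded random parameter sets with a growing balanced state."""
    return pc.generate_fixtures(
        pc.FixtureSpec(n_sets=20, seed=20160511)).parameter_sets


def params_strategy(*, allow_degradation=True, min_m=2.0):
    """Hypothesis strategy over valid PTR parameter sets."""
    pos = dict(allow_nan=False, allow_infinity=False)
    d = st.floats(0.0, 1.0, **pos) if allow_degradation else st.just(0.0)
    return st.builds(
        pc.PTRParameters,
        K_P=st.floats(1.0, 1e4, **pos),
        k=st.floats(1e-5, 1e-2, **pos),
        m_T=st.floats(min_m, 1e5, **pos),
        m_R=st.floats(min_m, 1e5, **pos),
        d_T=d, d_R=d,
        v_P=st.floats(1e-9, 1e-7, **pos),
        v_T=st.floats(0.0, 1e-7, **pos),
        v_R=st.floats(0.0, 1e-7, **pos),
        f_R=st.floats(0.01, 0.99, **pos),
    )
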