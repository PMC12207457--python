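import pytest

from crdlab import StudyDesign, default_config, generate_study


@pytest.fixture(scope="session")
def cfg3():
    return default_config(3)


@pytest.fixture(scope="session")
def cfg5():
    return default_config(5)


@pytest.fixture(scope="session")
def small_design():
    """A 10-groups-per-cell design, small enough for fast round trips."""
    return StudyDesign(
        n_groups={(3, True): 10, (3, False): 10, (5, True): 10, (5, False): 10},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return generate_study(small_design)
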