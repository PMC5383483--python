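import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sexflux as sf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table2_records():
    return sf.read_census(sf.fixture_path("table2_pairs"))


@pytest.fixture(scope="session")
def table2_trajectories(table2_records):
    return sf.build_trajectories(table2_records)


@pytest.fixture(scope="session")
def table1_trajectories():
    return sf.build_trajectories(sf.read_census(sf.fixture_path("table1_trajectories")))


@pytest.fixture(scope="session")
def pooled_counts(table2_trajectories):
    return sf.count_transitions(
        table2_trajectories, sf.POOLED_STATES, pooling=sf.POOL_TO_HALL
    )


@pytest.fixture(scope="session")
def counts6(table2_trajectories):
    return sf.count_transitions(table2_trajectories, sf.EXPRESSED_STATES)


def make_trajectory(states, start_year=2010, individual_id="ind", plot_id="P1"):
    """Trajectory over consecutive years from a plain state list."""
    return sf.Trajectory(
        individual_id=individual_id,
        plot_id=plot_id,
        observations=tuple((start_year + i, s) for i, s in enumerate(states)),
    )


@pytest.fixture
def trajectory_factory():
    return make_trajectory
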