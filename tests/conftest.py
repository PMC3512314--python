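import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pullwork as pw

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> pw.PullConfig:
    return pw.PullConfig()


@pytest.fixture(scope="session")
def viscous_config(default_config) -> pw.PullConfig:
    return dataclasses.replace(
        default_config, potential=pw.BindingPotential(form="flat"),
        seed=default_config.seed + 1)


@pytest.fixture(scope="session")
def bound_set(default_config) -> pw.ReplicaSet:
    return pw.simulate_replica_set(default_config, label="bound")


@pytest.fixture(scope="session")
def viscous_set(viscous_config) -> pw.ReplicaSet:
    return pw.simulate_replica_set(viscous_config, label="viscous")


def make_trajectory(times, spring_end, position, force,
                    **meta_kwargs) -> pw.PullTrajectory:
    """Hand-built 1-D trajectory with default metadata, for unit tests."""
    meta = pw.TrajectoryMeta(
        spring_k=meta_kwargs.pop("spring_k", 10.0),
        pull_rate_v=meta_kwargs.pop("pull_rate_v", 1.0),
        temperature_T=meta_kwargs.pop("temperature_T", 1.0),
        **meta_kwargs)
    return pw.PullTrajectory(
        times=np.asarray(times, dtype=float),
        spring_end=np.asarray(spring_end, dtype=float),
        position=np.asarray(position, dtype=float).reshape(len(times), -1),
        force=np.asarray(force, dtype=float).reshape(len(times), -1),
        meta=meta)
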