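import dataclasses

import pytest

from mapse3d import AnnulusMotionParams, run_pipeline, simulate_recording


@pytest.fixture(scope="session")
def noise_free_params():
    return AnnulusMotionParams(noise_sd=0.0, dropout_prob=0.0, outlier_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_recording(noise_free_params):
    return simulate_recording(noise_free_params)


@pytest.fixture(scope="session")
def noise_free_result(noise_free_recording):
    stream, _ = noise_free_recording
    return run_pipeline(stream)


@pytest.fixture(scope="session")
def default_recording():
    return simulate_recording(AnnulusMotionParams(seed=7))


def volumes_per_cycle(params: AnnulusMotionParams) -> int:
    import math

    return math.ceil(params.volume_rate * 60.0 / params.heart_rate)
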