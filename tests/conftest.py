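import numpy as np
import pytest

from ebusdepot.simulate import SimulationConfig, ConeSpec, simulate_video, annotation_for


def small_config(**overrides) -> SimulationConfig:
    """Compact phantom for fast unit tests: 120x120 px, 10 fps, 6 s."""
    defaults = dict(
        frame_rate=10.0,
        duration=6.0,
        image_size=(120, 120),
        px_per_cm=40.0,
        cone=ConeSpec(apex=(0.0, 60.0), opening_deg=70.0, radius_cm=2.9),
        needle_tip=(40, 60),
        needle_angle_deg=90.0,
        t0=1.0,
        a=0.04,
        b=0.6,
        c=0.0,
        speckle_scale=0.0,
        heartbeat_amp=0.0,
        true_retention=0.08,
        injected_volume_ml=8.0,
        rng_seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noiseless phantom video + ground truth (shared, read-only)."""
    config = small_config()
    video, truth = simulate_video(config)
    return config, video, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Phantom with default speckle and heartbeat (shared, read-only)."""
    config = small_config(speckle_scale=0.3, heartbeat_amp=0.05, rng_seed=7)
    video, truth = simulate_video(config)
    return config, video, truth


@pytest.fixture(scope="session")
def depot_free_sim():
    """Speckle-only phantom without any depot (a = 0)."""
    config = small_config(a=0.0, speckle_scale=0.3, heartbeat_amp=0.05, rng_seed=11)
    video, truth = simulate_video(config)
    return config, video, truth


@pytest.fixture
def annotation(noiseless_sim):
    config, _, _ = noiseless_sim
    return annotation_for(config, "SIM01")


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
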